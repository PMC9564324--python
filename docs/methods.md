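# Methods

This note records the models, parameter choices and numerical conventions
behind `wtint`, and what the synthetic-cohort tests do and do not show
about real data.

## Coordinates and interval conventions

All intervals are 0-based half-open internally; VCF I/O converts to
1-based inclusive positions. Reciprocal overlap of two intervals is
min(overlap/len(a), overlap/len(b)); it is 0 across chromosomes and
undefined (an error) for empty intervals. Breakends and insertions have no
meaningful length, so they are compared by per-breakpoint distance
(≤ 100 bp) with matching orientations instead.

## SV consensus

The filter chain applies, in order: supporting reads ≥ 7; removal at
reciprocal overlap strictly > 0.9 with a same-type common population
variant; cross-caller merging at reciprocal overlap ≥ 0.5 with
single-linkage connected components and a ≥ 2 distinct-caller requirement;
allele fraction strictly > 0.1 on the consensus. Strictness of each
comparison follows the wording of the underlying protocol ("at least
seven", "> 90%", "50% overlap", "> 0.1"). Design choices where the
protocol is silent:

* **Single linkage, not cliques.** Components are the simplest
  deterministic reading of pairwise-overlap merging; a greedy clique mode
  is available (`merge_callers(..., clique=True)`) for sensitivity checks.
* **Consensus allele fraction = maximum over members** — conservative
  toward retaining true somatic events.
* **Consensus coordinates = per-end medians** over members, clamped to the
  member hull; deterministic and independent of caller input order.

## CN summarization, binning, clustering

Interval summaries are overlap-length-weighted means of segment CR (and
MAF where present); with complete coverage this equals the per-base mean
exactly, which the test suite asserts against a brute-force expansion
oracle. Gain/loss calls use strict thresholds CR > 0.2 / CR < −0.2; the
boundary value is neutral. Uncovered genome inside a 1 Mbp bin is ignored
(covered-length weighting) rather than imputed as neutral, so focal
events in sparsely covered bins are not diluted; fully uncovered bins are
0. Bins overlapping excluded (centromere-analog) regions are dropped from
the cohort-wide bin universe.

Profile clustering is complete-linkage agglomeration on Euclidean
distance. The cluster number is chosen by an explicit elbow rule — the k
in 2..k_max−1 maximizing the second difference WSS(k−1) − 2·WSS(k) +
WSS(k+1), with WSS(1) the total sum of squares and ties resolved to the
smaller k — because "read the elbow off the plot" is not reproducible.
The genome-altered fraction uses the full autosomal genome length as its
denominator (not callable length), the simplest reproducible definition.

Arm "abundance" groups collect gained arms whose weighted CR and MAF agree
within tolerances (default 0.05 each, single-linkage closure); arms in one
group are compatible with a single underlying event. The tolerances are
configuration, not protocol values.

## Expression normalization and NMF subtyping

Normalization is median-of-ratios size factors (geometric-mean reference
over genes expressed in all samples) followed by log2(count/sf + 1). This
is a documented approximation of the reference variance-stabilizing
transformation: it is monotone in counts, removes depth differences, and
compresses the mean-variance relationship, which is all the downstream
statistics require. `NormalizedMatrix.from_values` accepts an externally
computed vst matrix for exact-parity runs.

NMF minimizes Frobenius error with multiplicative updates (uniform random
non-negative initialization scaled to the matrix mean, ε = 1e-10 guards,
convergence when the relative error improvement falls below 1e-5, cap 300
iterations). The error trajectory is recorded and is non-increasing, which
a property test asserts; an independent cross-check compares the final
error against scikit-learn's MU solver. Rank selection follows consensus
clustering: per candidate k (default 2–6), 30 seeded restarts, sample
co-clustering by argmax of H, consensus matrix C, cophenetic correlation
of 1 − C under average-linkage; the chosen k is the last one before the
coefficient first strictly decreases. A degenerate constant consensus is
scored 1.0 when fully co-clustered and 0.0 otherwise. Genes are assigned
to the profile of maximum basis weight; within a profile, genes rank by
l2fc = mean(vst in the profile's cluster) − mean(vst outside).

Variable-gene selection ranks by variance of normalized values (ties by
gene id) after excluding X/Y/MT-analog genes. On the miniature genomes
used throughout (500–2,000 genes), the analysis-scale default is the top
200 genes — the desk-scale analog of selecting the most variable ~10,000
of ~20,000 genes on a real transcriptome. As in the full-scale protocol,
this selection is load-bearing: planted subtype markers are a small
fraction of all genes, and Frobenius NMF on the unselected matrix is
dominated by high-baseline noise genes.

## nz-score, Wnt score, integration statistics

The nz-score reference set is *per-gene* CN-neutral tumors (a global-neutral
mode would conflate chromosomes); it uses the sample (n−1) standard
deviation and is undefined — flagged, not silently zero — when fewer than
two neutral tumors exist or their sd is 0. The Wnt score is the per-tumor
mean vst over the Wnt gene set, min-max scaled across the cohort; a
constant raw score yields all-zero scores with a warning.

The dosage test runs per gene and direction (gain/loss separately) when
≥ 3 tumors carry the alteration and ≥ 2 are neutral: two-sided Wilcoxon
rank-sum (exact enumeration when the pooled size is ≤ 10 and tie-free,
normal approximation with tie and continuity correction otherwise — a
thin dispatch over `scipy.stats.mannwhitneyu`, oracle-checked against
explicit enumeration), BH adjustment jointly across all gene×direction
tests, significance at q < 0.2 and |l2fc| > 0.138 where 0.138 =
round(log2(1.10), 3) encodes a 10% change on the log2 scale.

The co-occurrence funnel considers upregulation only (NMF components are
non-negative). "CN/SV altered" in a tumor means a gene-body gain call or
any SV breakpoint within 1 Mbp of the gene span, measured from the nearest
span boundary, inclusive. The reference stage ("expressed genes with a
recurrent CN/SV") defines expressed as cohort mean vst ≥ 1.0, an
operational choice where the protocol gives none. Gene labels: direct
evidence (non-benign SNV in the gene body; SV breakpoint inside the gene)
needs no expression support, so DNA-only tumors can receive it; indirect
evidence (spanning/nearby SV, gene-body gain/loss) requires |nz| > 1.98
without enforcing sign concordance with the CN direction — the requirement
is *a* change in expression, not a concordant one.

## 1q mechanism classification

Rules fire first-match in the order isochromosome-like → BFB-like →
inverted duplication → arm gain with subsequent SVs → arm gain without
SVs, mirroring decreasing specificity of evidence. "Full arm" means
≥ 90% of the arm's length is called gained (or lost); the CN-boundary /
SV-breakpoint correspondence tolerance is 10 kb (segmentation resolution;
configurable). For the isochromosome rule, a 1p loss and a 1q gain cannot
share a CR, so "same abundance" is operationalized as consistency of the
implied clonal cell fractions: f_loss = 2 − 2^(1+CR_p) and
f_gain = 2^(1+CR_q) − 2 must agree within 0.2. Clonality inference
compares the observed CR of the gained region to log2((2 + c·purity)/2)
for c = 1..4 extra copies (tolerance 0.1); MAF, expected 1/(2 + purity),
is checked only for c = 1 where the minor copy number is determined.
Verdicts: clonal on a match, subclonal when CR falls below the one-copy
expectation by more than the tolerance, indeterminate when arm coverage
is < 0.5 or CR exceeds all tested expectations. Purity is an input
(default 1.0); no purity estimation is performed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes on
a miniature genome (four 50 Mbp chromosomes named 1, 2, 3, 11; arms at
0–48% and 52–100% with a centromeric excluded gap; genes of 10–100 kb
placed uniformly, 3% coding). Allele accounting is exact before noise:
a region of copy state (total t, minor m) at purity p emits
CR = log2(((1−p)·2 + p·t)/2) and MAF = ((1−p) + p·m)/((1−p)·2 + p·t),
then Gaussian noise (sd 0.02 by default) per segment. Planted patterns:
iso-1q (1p→1 copy, 1q→3), BFB-like (proximal 60% of 1q→3 with a fold-back
inversion at the boundary, distal loss), inverted duplication (1q 15–75%
→3 with a matching inverted DUP SV), clean and SV-bearing full-arm gains
(the latter with a mid-arm translocation to chromosome 2), gains of
chromosomes 2+3, 11p copy-neutral LOH, and neutral. Default purity is 1.0
(real purities are unknown; the parameter is explicit everywhere).

SV observation: each of three caller profiles (sensitivity 0.95/0.90/0.85,
breakpoint jitter sd 10/20/30 bp, false positives at 0.02–0.03 per Mbp,
Poisson supporting reads with mean 25 for true calls and 8 for false ones)
independently re-emits the truth; 30% of a 30-entry population-SV database
leaks into every caller's output at AF ≈ 0.5 for the population filter to
remove. Somatic allele fractions are purity/2 plus noise. Each tumor also
carries four background somatic SVs on chromosomes 2/3 (kept off 1 and 11
so mechanism truth stays clean).

Expression: counts[g, t] ~ NB(mean = baseline_g × cluster_effect ×
dosage, dispersion 0.1 shared across genes), with lognormal baselines
(log-mean log 100, log-sd 1), four planted clusters of 30 disjoint marker
genes each upregulated 3-fold in their own cluster (a realistic subtype
marker effect), and dosage = 1.4 per extra gene-body copy. SNVs include
genome-wide passengers with mixed impact, dbSNP-only germline leaks, an
in-COSMIC dbSNP keeper, low-AF artifacts, normal-contaminated calls and
occasional HIGH-impact drivers in cancer-set genes, exercising every
confidence-filter clause.

What the generator does **not** emulate: read-level data, segmentation
error beyond Gaussian CR/MAF noise, correlated caller errors, subclonal
architecture and clonal evolution, realistic trinucleotide mutation
spectra, gene-length/GC expression biases, or cluster structure spread
over thousands of weakly informative genes as in real transcriptomes.
Consequently, passing recovery tests demonstrates correctness of the
algorithms under the stated noise model — not that real cohorts of this
size would yield equally clean cluster or mechanism calls.

## Problem sizes and determinism

Test and acceptance workloads use desk-scale cohorts chosen to exercise
every code path: 22 tumors × 2,000 genes for expression recovery (five
seeds), 30 tumors for CN cluster recovery (five seeds), 20 five-tumor
cohorts for mechanism recovery, 12 tumors end-to-end. The mechanism
recovery suite runs its callers at sensitivity 1.0 (default jitter and CN
noise) so that it measures the rule cascade rather than binomial caller
dropout, which the ≥ 95% consensus-recovery check covers at the default
sensitivities. Every stochastic component draws from
`numpy.random.default_rng` seeded from a single configured seed; pipeline
reruns with the same configuration are byte-identical, recorded as
checksums in the run manifest.

## Known limitations

* The vst approximation differs numerically from the reference
  transformation; rank-based statistics are unaffected, but l2fc values
  are comparable only within a run (the external-vst hook restores exact
  parity when needed).
* BND merging uses a fixed 100 bp window and does not model caller-specific
  breakpoint uncertainty intervals (CIPOS).
* The clonality model assumes one dominant clone and known purity; it does
  not fit mixtures.
* Cytoband-level summaries are supported through arbitrary intervals, but
  the miniature annotation only materializes arms and an excluded gap.
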