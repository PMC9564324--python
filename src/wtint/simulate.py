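"""Synthetic tumor-cohort generator with full ground truth.

Emulates the joint genomic/transcriptomic structure the integrated
analysis assumes: per-tumor CN segment profiles for planted event
patterns (isochromosome 1q, BFB-like partial 1q gain, inverted
duplication, clean and SV-bearing arm gains, multi-chromosome gains,
copy-neutral LOH of 11p, neutral), multi-caller SV call sets with
breakpoint jitter / false positives / germline leakage, annotated somatic
SNVs, and negative-binomial expression counts with planted expression
clusters and multiplicative CN dosage effects.

Allele accounting before noise is exact: a region of integer copy state
(total t, minor m) in a tumor of purity p is emitted with
CR = log2(((1-p)*2 + p*t)/2) and MAF = ((1-p) + p*m)/((1-p)*2 + p*t).
Every observation traces to a truth entry or a declared noise process,
and all generators are deterministic under the configured seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, generate_annotation, write_annotation
from .cn import CNSegment
from .snv import SmallVariant
from .sv import SVCall

PATTERNS = (
    "iso1q",
    "bfb_partial_1q",
    "invdup_1q",
    "arm_gain_clean_1q",
    "arm_gain_plus_sv_1q",
    "multi_gain",
    "cnloh_11p",
    "neutral",
)

#: planted mechanism implied by each 1q+ pattern
PATTERN_MECHANISM = {
    "iso1q": "isochromosome_like",
    "bfb_partial_1q": "bfb_like",
    "invdup_1q": "inverted_duplication",
    "arm_gain_clean_1q": "arm_gain_no_sv",
    "arm_gain_plus_sv_1q": "arm_gain_with_subsequent_sv",
}

CLUSTERS = ("EX1", "EX2", "EX3", "EX4")


@dataclass(frozen=True)
class CNEvent:
    """Planted integer copy state over a region (before purity/noise)."""

    chrom: str
    start: int
    end: int
    total: int
    minor: int


@dataclass(frozen=True)
class CallerProfile:
    name: str
    sensitivity: float = 0.9
    fp_rate_per_mb: float = 0.02
    breakpoint_jitter_sd: float = 20.0
    read_mean: float = 25.0
    fp_read_mean: float = 8.0


DEFAULT_CALLERS = (
    CallerProfile("callerA", 0.95, 0.02, 10.0),
    CallerProfile("callerB", 0.90, 0.02, 20.0),
    CallerProfile("callerC", 0.85, 0.03, 30.0),
)


@dataclass
class CohortConfig:
    seed: int = 0
    n_tumors: int = 22
    patterns: list[str] = field(default_factory=list)
    clusters: list[str] = field(default_factory=list)
    purity: list[float] = field(default_factory=list)
    has_rna: list[bool] = field(default_factory=list)
    dosage_effect: float = 1.4
    nb_dispersion: float = 0.1
    marker_fold_change: float = 3.0
    n_marker_genes: int = 30
    cn_noise_sd: float = 0.02
    caller_profiles: tuple[CallerProfile, ...] = DEFAULT_CALLERS
    n_genes: int = 500
    n_pop_svs: int = 30
    pop_leak_fraction: float = 0.3
    n_background_svs: int = 4
    n_passenger_snvs: int = 120
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.patterns:
            self.patterns = default_patterns(self.n_tumors)
        if not self.clusters:
            self.clusters = [CLUSTERS[i % 4] for i in range(self.n_tumors)]
        if not self.purity:
            self.purity = [1.0] * self.n_tumors
        if not self.has_rna:
            self.has_rna = [True] * self.n_tumors
        for name, lst in (("patterns", self.patterns), ("clusters", self.clusters),
                          ("purity", self.purity), ("has_rna", self.has_rna)):
            if len(lst) != self.n_tumors:
                raise ValueError(f"{name} must have length n_tumors")
        for p in self.patterns:
            if p not in PATTERNS:
                raise ValueError(f"unknown CN pattern {p!r}")
        for p in self.purity:
            if not 0.0 < p <= 1.0:
                raise ValueError("purity must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if len(self.caller_profiles) < 2:
            raise ValueError("need >= 2 caller profiles")


def default_patterns(n_tumors: int) -> list[str]:
    """Pattern mix mirroring the cohort composition: ~27% 1q+ tumors with
    one tumor per mechanism class, plus multi-gain, 11p CN-LOH and neutral
    tumors."""
    base = [
        "iso1q", "bfb_partial_1q", "invdup_1q",
        "arm_gain_clean_1q", "arm_gain_clean_1q", "arm_gain_plus_sv_1q",
        "multi_gain", "multi_gain", "multi_gain",
        "cnloh_11p", "cnloh_11p", "cnloh_11p",
    ]
    if n_tumors <= len(base):
        return base[:n_tumors]
    return base + ["neutral"] * (n_tumors - len(base))


@dataclass
class TumorTruth:
    sample: str
    pattern: str
    purity: float
    cluster: str
    has_rna: bool
    cn_events: list[CNEvent] = field(default_factory=list)
    true_svs: list[SVCall] = field(default_factory=list)
    mechanism: str | None = None


@dataclass
class TruthSet:
    tumors: dict[str, TumorTruth]
    marker_genes: dict[str, list[str]]  # cluster -> planted upregulated genes

    def mechanisms(self) -> dict[str, str]:
        return {s: t.mechanism for s, t in self.tumors.items() if t.mechanism}


@dataclass
class SyntheticCohort:
    config: CohortConfig
    annotation: GenomeAnnotation
    truth: TruthSet
    cn_segments: dict[str, list[CNSegment]]
    sv_callsets: dict[str, dict[str, list[SVCall]]]  # sample -> caller -> calls
    popdb: list[SVCall]
    snvs: dict[str, list[SmallVariant]]
    counts: pd.DataFrame  # genes x samples (RNA samples only)

    @property
    def samples(self) -> list[str]:
        return list(self.truth.tumors)


# ---- CN truth and segments ---------------------------------------------


def _plant_pattern(
    pattern: str, annotation: GenomeAnnotation, sample: str
) -> tuple[list[CNEvent], list[SVCall], str | None]:
    """Copy-state events plus the true SVs implied by a pattern."""
    events: list[CNEvent] = []
    svs: list[SVCall] = []
    mechanism = PATTERN_MECHANISM.get(pattern)
    p1 = annotation.arm("1p")
    q1 = annotation.arm("1q")
    if pattern == "iso1q":
        events = [CNEvent("1", p1.start, p1.end, 1, 0), CNEvent("1", q1.start, q1.end, 3, 1)]
    elif pattern == "bfb_partial_1q":
        fold = q1.start + int(0.6 * (q1.end - q1.start))
        events = [CNEvent("1", q1.start, fold, 3, 1), CNEvent("1", fold, q1.end, 1, 0)]
        svs = [
            SVCall(f"{sample}_bfb_inv", "truth", "INV", "1", fold - 200, fold + 200,
                   inverted=True)
        ]
    elif pattern == "invdup_1q":
        a = q1.start + int(0.15 * (q1.end - q1.start))
        b = q1.start + int(0.75 * (q1.end - q1.start))
        events = [CNEvent("1", a, b, 3, 1)]
        svs = [SVCall(f"{sample}_invdup", "truth", "DUP", "1", a, b, inverted=True)]
    elif pattern == "arm_gain_clean_1q":
        events = [CNEvent("1", q1.start, q1.end, 3, 1)]
    elif pattern == "arm_gain_plus_sv_1q":
        events = [CNEvent("1", q1.start, q1.end, 3, 1)]
        mid = q1.start + int(0.4 * (q1.end - q1.start))
        svs = [
            SVCall(f"{sample}_tra", "truth", "BND", "1", mid, mid + 1,
                   chrom2="2", pos2=10_000_000, orient1="+", orient2="-")
        ]
    elif pattern == "multi_gain":
        for chrom in ("2", "3"):
            for arm in annotation.arms_of(chrom):
                events.append(CNEvent(chrom, arm.start, arm.end, 3, 1))
    elif pattern == "cnloh_11p":
        p11 = annotation.arm("11p")
        events = [CNEvent("11", p11.start, p11.end, 2, 0)]
    elif pattern == "neutral":
        pass
    else:
        raise ValueError(f"unsupported pattern {pattern!r}")
    return events, svs, mechanism


def expected_cr(total: int, purity: float) -> float:
    return math.log2(((1 - purity) * 2 + purity * total) / 2)


def expected_maf(total: int, minor: int, purity: float) -> float:
    return ((1 - purity) + purity * minor) / ((1 - purity) * 2 + purity * total)


def generate_cn_profile(
    pattern: str,
    annotation: GenomeAnnotation,
    purity: float,
    seed: int,
    noise_sd: float = 0.02,
    sample: str = "T00",
) -> list[CNSegment]:
    """CN segments for one tumor: arms split at planted event boundaries,
    exact allele accounting at the given purity, Gaussian noise per segment."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    events, _, _ = _plant_pattern(pattern, annotation, sample)
    rng = np.random.default_rng(seed)
    return _segments_from_events(events, annotation, purity, rng, noise_sd, sample)


def _segments_from_events(
    events: list[CNEvent],
    annotation: GenomeAnnotation,
    purity: float,
    rng: np.random.Generator,
    noise_sd: float,
    sample: str,
) -> list[CNSegment]:
    segments: list[CNSegment] = []
    for arm in annotation.arms:
        cuts = {arm.start, arm.end}
        for ev in events:
            if ev.chrom == arm.chrom:
                for pos in (ev.start, ev.end):
                    if arm.start < pos < arm.end:
                        cuts.add(pos)
        edges = sorted(cuts)
        for s, e in zip(edges, edges[1:]):
            total, minor = 2, 1
            for ev in events:
                if ev.chrom == arm.chrom and ev.start <= s and e <= ev.end:
                    total, minor = ev.total, ev.minor
                    break
            cr = expected_cr(total, purity) + float(rng.normal(0.0, noise_sd))
            maf = expected_maf(total, minor, purity) + float(rng.normal(0.0, noise_sd))
            maf = min(max(maf, 0.0), 0.5)
            segments.append(
                CNSegment(sample, arm.chrom, s, e, cr, maf, max(1, (e - s) // 10_000))
            )
    segments.sort(key=lambda x: (x.chrom, x.start))
    return segments


# ---- SV call sets -------------------------------------------------------


def generate_popdb(annotation: GenomeAnnotation, n: int, seed: int) -> list[SVCall]:
    """Common population SVs (germline CNV/inversion analogs)."""
    rng = np.random.default_rng(seed)
    chroms = annotation.chromosomes
    out = []
    for i in range(n):
        chrom, length = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(20_000, 300_000))
        start = int(rng.integers(0, length - size))
        svtype = ["DEL", "DUP", "INV"][int(rng.integers(3))]
        out.append(SVCall(f"pop{i:03d}", "popdb", svtype, chrom, start, start + size,
                          supporting_reads=0, allele_fraction=0.5))
    return out


def _random_background_svs(
    annotation: GenomeAnnotation, n: int, rng: np.random.Generator, sample: str
) -> list[SVCall]:
    # background somatic SVs kept off chr1/chr11 so mechanism truth stays clean
    chroms = [(c, l) for c, l in annotation.chromosomes if c not in ("1", "11")]
    out = []
    for i in range(n):
        chrom, length = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(100_000, 800_000))
        start = int(rng.integers(0, length - size))
        svtype = ["DEL", "DUP", "INV"][int(rng.integers(3))]
        out.append(SVCall(f"{sample}_bg{i}", "truth", svtype, chrom, start, start + size))
    return out


def generate_sv_callsets(
    true_svs: list[SVCall],
    caller_profiles: tuple[CallerProfile, ...],
    seed: int,
    annotation: GenomeAnnotation,
    popdb: list[SVCall] | None = None,
    pop_leak_fraction: float = 0.0,
    somatic_af: float = 0.5,
) -> dict[str, list[SVCall]]:
    """Noisy per-caller observations of the planted SVs.

    Each caller sees a true SV with probability `sensitivity`, with
    N(0, jitter_sd) coordinate error, Poisson supporting reads (min 1) and
    the somatic allele fraction plus noise. False positives arrive at
    `fp_rate_per_mb` per Mbp of genome; a sampled subset of population SVs
    leaks into every caller's output as germline contamination (high AF),
    to be removed downstream by the population filter.
    """
    if not caller_profiles:
        raise ValueError("empty caller_profiles")
    rng = np.random.default_rng(seed)
    genome_mb = sum(l for _, l in annotation.chromosomes) / 1e6
    popdb = popdb or []
    n_leak = int(round(pop_leak_fraction * len(popdb)))
    leak_idx = rng.choice(len(popdb), size=n_leak, replace=False) if n_leak else []
    leaked = [popdb[int(i)] for i in leak_idx]

    out: dict[str, list[SVCall]] = {}
    for prof in caller_profiles:
        calls: list[SVCall] = []
        counter = 0

        def emit(sv: SVCall, af: float, read_mean: float) -> None:
            nonlocal counter
            jit = lambda x: max(0, int(round(x + rng.normal(0.0, prof.breakpoint_jitter_sd))))
            reads = max(1, int(rng.poisson(read_mean)))
            af_obs = float(np.clip(af + rng.normal(0.0, 0.02), 0.01, 1.0))
            if sv.svtype == "BND":
                p1 = jit(sv.start)
                calls.append(SVCall(
                    f"{prof.name}_{counter}", prof.name, "BND", sv.chrom, p1,
                    p1 + 1, reads, af_obs, sv.inverted, sv.chrom2,
                    jit(sv.pos2), sv.orient1, sv.orient2,
                ))
            else:
                s = jit(sv.start)
                e = jit(sv.end)
                if e <= s:
                    e = s + 1
                calls.append(SVCall(
                    f"{prof.name}_{counter}", prof.name, sv.svtype, sv.chrom, s, e,
                    reads, af_obs, sv.inverted,
                ))
            counter += 1

        for sv in true_svs:
            if rng.random() < prof.sensitivity:
                emit(sv, somatic_af, prof.read_mean)
        for sv in leaked:
            if rng.random() < 0.95:
                emit(sv, 0.5, prof.read_mean)
        n_fp = int(rng.poisson(prof.fp_rate_per_mb * genome_mb))
        for i in range(n_fp):
            chrom, length = annotation.chromosomes[int(rng.integers(len(annotation.chromosomes)))]
            size = int(rng.integers(1_000, 100_000))
            start = int(rng.integers(0, max(1, length - size)))
            svtype = ["DEL", "DUP", "INV"][int(rng.integers(3))]
            af = float(rng.uniform(0.02, 0.3))
            reads = max(1, int(rng.poisson(prof.fp_read_mean)))
            calls.append(SVCall(f"{prof.name}_fp{i}", prof.name, svtype, chrom, start,
                                start + size, reads, af))
        out[prof.name] = calls
    return out


# ---- SNVs ---------------------------------------------------------------

_BASES = "ACGT"


def _random_snv(rng: np.random.Generator, annotation: GenomeAnnotation, sample: str,
                gene=None, **overrides) -> SmallVariant:
    if gene is None:
        chrom, length = annotation.chromosomes[int(rng.integers(len(annotation.chromosomes)))]
        pos = int(rng.integers(1, length))
        gene_id = None
        for g in annotation.genes_on(chrom):
            if g.start <= pos - 1 < g.end:
                gene_id = g.gene_id
                break
    else:
        chrom = gene.chrom
        pos = int(rng.integers(gene.start + 1, gene.end + 1))
        gene_id = gene.gene_id
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
    fields = dict(
        sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, gene_id=gene_id,
        tumor_af=float(np.clip(rng.normal(0.4, 0.1), 0.02, 0.95)),
        tumor_depth=int(rng.poisson(60)), normal_depth=int(rng.poisson(60)),
        normal_alt_reads=0, impact="MODIFIER", sift_polyphen_benign=False,
        in_dbsnp=False, in_cosmic=False,
    )
    fields.update(overrides)
    return SmallVariant(**fields)


def generate_snvs(
    annotation: GenomeAnnotation, sample: str, seed: int, n_passengers: int = 120,
    driver_gene=None,
) -> list[SmallVariant]:
    """Somatic SNVs/indels for one tumor: passengers across the genome
    (mixed impacts), a few germline/dbSNP leaks and low-AF artifacts that
    the confidence filters must remove, and optionally a HIGH-impact
    driver in a given gene."""
    rng = np.random.default_rng(seed)
    variants: list[SmallVariant] = []
    impacts = ["MODIFIER", "LOW", "MODERATE", "HIGH"]
    probs = [0.55, 0.2, 0.2, 0.05]
    for _ in range(n_passengers):
        impact = impacts[int(rng.choice(4, p=probs))]
        variants.append(_random_snv(rng, annotation, sample, impact=impact))
    # dbSNP-only germline leaks (should be removed) and one dbSNP+COSMIC keeper
    for _ in range(8):
        variants.append(_random_snv(rng, annotation, sample, in_dbsnp=True))
    variants.append(_random_snv(rng, annotation, sample, in_dbsnp=True, in_cosmic=True,
                                impact="MODERATE"))
    # low-AF artifacts and normal-contaminated calls
    for _ in range(5):
        variants.append(_random_snv(rng, annotation, sample, tumor_af=float(rng.uniform(0.01, 0.1))))
    for _ in range(3):
        variants.append(_random_snv(rng, annotation, sample, normal_alt_reads=int(rng.integers(1, 5))))
    if driver_gene is not None:
        variants.append(_random_snv(rng, annotation, sample, gene=driver_gene, impact="HIGH",
                                    in_cosmic=True))
    return variants


# ---- expression ---------------------------------------------------------


def _extra_copies_per_gene(
    annotation: GenomeAnnotation, events: list[CNEvent]
) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in annotation.genes:
        extra = 0
        mid = (g.start + g.end) // 2
        for ev in events:
            if ev.chrom == g.chrom and ev.start <= mid < ev.end:
                extra = ev.total - 2
                break
        if extra:
            out[g.gene_id] = extra
    return out


def generate_expression(
    cluster_labels: dict[str, str],
    annotation: GenomeAnnotation,
    cn_events: dict[str, list[CNEvent]],
    dosage_effect: float = 1.4,
    nb_dispersion: float = 0.1,
    seed: int = 0,
    marker_genes: dict[str, list[str]] | None = None,
    marker_fold_change: float = 3.0,
    n_marker_genes: int = 30,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Negative-binomial counts with planted clusters and CN dosage.

    counts[g, t] ~ NB(mean = baseline_g * cluster_effect * dosage, disp)
    with dosage = dosage_effect ** (extra copies over the gene body) and
    cluster_effect = marker_fold_change for the tumor's own cluster's
    marker genes. Marker sets are disjoint; returned alongside the matrix.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in annotation.genes]
    samples = list(cluster_labels)
    clusters = sorted(set(cluster_labels.values()))
    if marker_genes is None:
        pool = list(genes)
        rng.shuffle(pool)
        marker_genes = {}
        for i, cl in enumerate(clusters):
            marker_genes[cl] = sorted(pool[i * n_marker_genes:(i + 1) * n_marker_genes])
    marker_of: dict[str, str] = {}
    for cl, ms in marker_genes.items():
        for m in ms:
            if m in marker_of:
                raise ValueError("planted marker sets must be disjoint")
            marker_of[m] = cl

    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(genes)))
    extra = {s: _extra_copies_per_gene(annotation, cn_events.get(s, [])) for s in samples}
    r = 1.0 / nb_dispersion
    mat = np.zeros((len(genes), len(samples)), dtype=int)
    for j, s in enumerate(samples):
        cl = cluster_labels[s]
        for i, g in enumerate(genes):
            mean = baseline[i]
            if marker_of.get(g) == cl:
                mean *= marker_fold_change
            e = extra[s].get(g, 0)
            if e:
                mean *= dosage_effect ** e
            p = r / (r + mean)
            mat[i, j] = int(rng.negative_binomial(r, p))
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    return counts, marker_genes


# ---- whole cohort -------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete cohort (annotation, CN, SVs, SNVs, expression)."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=6 + 3 * config.n_tumors)
    annotation = generate_annotation(int(seeds[0]), n_genes=config.n_genes)
    popdb = generate_popdb(annotation, config.n_pop_svs, int(seeds[1]))
    cancer_genes = annotation.gene_sets.get("CANCER_GENES", [])

    tumors: dict[str, TumorTruth] = {}
    cn_segments: dict[str, list[CNSegment]] = {}
    sv_callsets: dict[str, dict[str, list[SVCall]]] = {}
    snvs: dict[str, list[SmallVariant]] = {}
    for i in range(config.n_tumors):
        sample = f"T{i + 1:02d}"
        pattern = config.patterns[i]
        purity = config.purity[i]
        events, true_svs, mechanism = _plant_pattern(pattern, annotation, sample)
        rng_i = np.random.default_rng(int(seeds[6 + 3 * i]))
        background = _random_background_svs(annotation, config.n_background_svs, rng_i, sample)
        all_true = true_svs + background
        cn_segments[sample] = _segments_from_events(
            events, annotation, purity, rng_i, config.cn_noise_sd, sample
        )
        sv_callsets[sample] = generate_sv_callsets(
            all_true, config.caller_profiles, int(seeds[6 + 3 * i + 1]), annotation,
            popdb=popdb, pop_leak_fraction=config.pop_leak_fraction,
            somatic_af=purity / 2,
        )
        driver = None
        if cancer_genes and i % 3 == 0:
            driver = annotation.gene(cancer_genes[i % len(cancer_genes)])
        snvs[sample] = generate_snvs(
            annotation, sample, int(seeds[6 + 3 * i + 2]),
            n_passengers=config.n_passenger_snvs, driver_gene=driver,
        )
        tumors[sample] = TumorTruth(
            sample, pattern, purity, config.clusters[i], config.has_rna[i],
            events, all_true, mechanism,
        )

    rna_samples = [s for s, t in tumors.items() if t.has_rna]
    counts, markers = generate_expression(
        {s: tumors[s].cluster for s in rna_samples},
        annotation,
        {s: tumors[s].cn_events for s in rna_samples},
        dosage_effect=config.dosage_effect,
        nb_dispersion=config.nb_dispersion,
        seed=int(seeds[2]),
        marker_fold_change=config.marker_fold_change,
        n_marker_genes=config.n_marker_genes,
    )
    truth = TruthSet(tumors, markers)
    return SyntheticCohort(config, annotation, truth, cn_segments, sv_callsets, popdb, snvs, counts)


# ---- serialization ------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text files (annotation, TSV, VCF, JSON)."""
    from .vcfio import write_sv_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation(cohort.annotation, outdir / "annotation")

    seg_rows = []
    for sample, segs in cohort.cn_segments.items():
        for s in segs:
            seg_rows.append([sample, s.chrom, s.start, s.end, s.log2_copy_ratio,
                             s.minor_allele_fraction, s.n_points])
    pd.DataFrame(
        seg_rows,
        columns=["sample", "chrom", "start", "end", "log2_copy_ratio",
                 "minor_allele_fraction", "n_points"],
    ).to_csv(outdir / "cn_segments.tsv", sep="\t", index=False)

    svdir = outdir / "sv"
    svdir.mkdir(exist_ok=True)
    for sample, callsets in cohort.sv_callsets.items():
        for caller, calls in callsets.items():
            write_sv_vcf(calls, svdir / f"{sample}.{caller}.vcf", cohort.annotation)
    write_sv_vcf(cohort.popdb, outdir / "popdb.vcf", cohort.annotation)

    snv_rows = []
    for sample, variants in cohort.snvs.items():
        for v in variants:
            snv_rows.append([sample, v.chrom, v.pos, v.ref, v.alt, v.gene_id or "",
                             v.tumor_af, v.tumor_depth, v.normal_depth,
                             v.normal_alt_reads, v.impact,
                             int(v.sift_polyphen_benign), int(v.in_dbsnp), int(v.in_cosmic)])
    pd.DataFrame(
        snv_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "gene_id", "tumor_af",
                 "tumor_depth", "normal_depth", "normal_alt_reads", "impact",
                 "sift_polyphen_benign", "in_dbsnp", "in_cosmic"],
    ).to_csv(outdir / "snvs.tsv", sep="\t", index=False)

    cohort.counts.to_csv(outdir / "counts.tsv", sep="\t")

    truth = {
        "marker_genes": cohort.truth.marker_genes,
        "tumors": {
            s: {
                "pattern": t.pattern,
                "purity": t.purity,
                "cluster": t.cluster,
                "has_rna": t.has_rna,
                "mechanism": t.mechanism,
                "cn_events": [asdict(e) for e in t.cn_events],
                "true_svs": [
                    {k: v for k, v in asdict(sv).items()} for sv in t.true_svs
                ],
            }
            for s, t in cohort.truth.tumors.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
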