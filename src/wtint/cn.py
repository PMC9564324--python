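"""Copy-number segment summarization, gain/loss calling, binning, clustering.

Segments carry a log2 copy ratio (CR; 0 = diploid-neutral) and optionally a
minor allele fraction (MAF; 0.5 = balanced). Summaries over arbitrary
intervals (arms, cytobands, gene bodies) are overlap-length-weighted
averages of the overlapping segments; gains and losses are called at a
strict +/- 0.2 CR threshold. Whole profiles are rasterized into 1 Mbp bins
(excluded regions dropped) and clustered hierarchically on Euclidean
distance with an elbow rule on within-cluster sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage  # noqa: F401 (cophenet used by expr)

from .annotation import GenomeAnnotation

#: strict CR threshold for calling a gain (> +0.2) or a loss (< -0.2)
CR_THRESHOLD = 0.2


@dataclass(frozen=True)
class CNSegment:
    sample: str
    chrom: str
    start: int
    end: int
    log2_copy_ratio: float
    minor_allele_fraction: float | None = None
    n_points: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment with start >= end on {self.chrom}")


@dataclass(frozen=True)
class IntervalSummary:
    interval: tuple[str, int, int]
    name: str
    weighted_cr: float | None
    weighted_maf: float | None
    covered_fraction: float
    call: str  # gain | loss | neutral | no_data


def call_from_cr(cr: float, threshold: float = CR_THRESHOLD) -> str:
    if cr > threshold:
        return "gain"
    if cr < -threshold:
        return "loss"
    return "neutral"


def summarize_interval(
    segments: list[CNSegment],
    interval: tuple[str, int, int],
    name: str = "",
    threshold: float = CR_THRESHOLD,
) -> IntervalSummary:
    """Overlap-weighted CR/MAF average of ``segments`` over ``interval``.

    Weights are overlap lengths; MAF is averaged over the covered length
    where MAF is present. Zero coverage yields call ``no_data`` with absent
    numeric fields.
    """
    chrom, istart, iend = interval
    if not istart < iend:
        raise ValueError("empty interval")
    w_cr = w = 0.0
    w_maf = wm = 0.0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        olap = min(seg.end, iend) - max(seg.start, istart)
        if olap <= 0:
            continue
        w += olap
        w_cr += olap * seg.log2_copy_ratio
        if seg.minor_allele_fraction is not None:
            wm += olap
            w_maf += olap * seg.minor_allele_fraction
    if w == 0:
        return IntervalSummary(interval, name, None, None, 0.0, "no_data")
    cr = w_cr / w
    maf = (w_maf / wm) if wm > 0 else None
    return IntervalSummary(interval, name, cr, maf, w / (iend - istart), call_from_cr(cr, threshold))


def summarize_arms(
    segments: list[CNSegment], annotation: GenomeAnnotation, threshold: float = CR_THRESHOLD
) -> dict[str, IntervalSummary]:
    return {
        arm.name: summarize_interval(segments, (arm.chrom, arm.start, arm.end), arm.name, threshold)
        for arm in annotation.arms
    }


def summarize_genes(
    segments: list[CNSegment], annotation: GenomeAnnotation, threshold: float = CR_THRESHOLD
) -> dict[str, IntervalSummary]:
    return {
        g.gene_id: summarize_interval(segments, (g.chrom, g.start, g.end), g.gene_id, threshold)
        for g in annotation.genes
    }


def gene_cn_status(
    segments_by_sample: dict[str, list[CNSegment]],
    annotation: GenomeAnnotation,
    threshold: float = CR_THRESHOLD,
) -> pd.DataFrame:
    """Genes x samples matrix of calls in {gain, loss, neutral, no_data}."""
    samples = sorted(segments_by_sample)
    data = {}
    for sample in samples:
        summ = summarize_genes(segments_by_sample[sample], annotation, threshold)
        data[sample] = {gid: s.call for gid, s in summ.items()}
    df = pd.DataFrame(data, columns=samples)
    return df.reindex([g.gene_id for g in annotation.genes])


def genome_altered_fraction(
    segments: list[CNSegment],
    annotation: GenomeAnnotation,
    threshold: float = CR_THRESHOLD,
) -> float:
    """Fraction of the autosomal genome in segments with |CR| > threshold."""
    autosomes = set(annotation.autosome_names())
    total = sum(length for chrom, length in annotation.chromosomes if chrom in autosomes)
    altered = sum(
        seg.end - seg.start
        for seg in segments
        if seg.chrom in autosomes and abs(seg.log2_copy_ratio) > threshold
    )
    return altered / total


@dataclass(frozen=True)
class ArmAbundanceClass:
    arm: str
    weighted_cr: float
    weighted_maf: float | None
    cr_minus_sample_max: float
    group_id: int


def arm_abundance_groups(
    arm_summaries: dict[str, IntervalSummary],
    tol_cr: float = 0.05,
    tol_maf: float = 0.05,
) -> list[ArmAbundanceClass]:
    """Group gained arms sharing the same abundance (CR and MAF within tol).

    Arms in one group are compatible with a single mutational event having
    produced them. Grouping is single-linkage (symmetric + transitive
    closure); each arm is annotated with its CR relative to the sample's
    maximum arm CR.
    """
    gained = [
        (name, s) for name, s in sorted(arm_summaries.items()) if s.call == "gain"
    ]
    if not gained:
        return []
    max_cr = max(s.weighted_cr for _, s in gained)
    n = len(gained)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            si, sj = gained[i][1], gained[j][1]
            if abs(si.weighted_cr - sj.weighted_cr) > tol_cr:
                continue
            if (
                si.weighted_maf is not None
                and sj.weighted_maf is not None
                and abs(si.weighted_maf - sj.weighted_maf) > tol_maf
            ):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    roots = sorted({find(i) for i in range(n)})
    group_of = {r: gi for gi, r in enumerate(roots)}
    return [
        ArmAbundanceClass(
            name, s.weighted_cr, s.weighted_maf, s.weighted_cr - max_cr, group_of[find(i)]
        )
        for i, (name, s) in enumerate(gained)
    ]


# ---- binned profiles and clustering ------------------------------------


def bin_universe(annotation: GenomeAnnotation, bin_size: int = 1_000_000) -> list[tuple[str, int, int]]:
    """Cohort-wide 1 Mbp bin grid over arms, dropping excluded-region bins."""
    bins = []
    for chrom, length in annotation.chromosomes:
        excluded = [(s, e) for c, s, e in annotation.excluded_regions if c == chrom]
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            if any(start < xe and xs < end for xs, xe in excluded):
                continue
            bins.append((chrom, start, end))
    return bins


def bin_profile(
    segments: list[CNSegment],
    annotation: GenomeAnnotation,
    bin_size: int = 1_000_000,
) -> pd.Series:
    """Per-bin covered-length-weighted mean CR; uncovered bins are 0.

    Only covered bases inside a bin contribute to its weighted mean, so a
    focal event in an otherwise uncallable bin is not diluted.
    """
    bins = bin_universe(annotation, bin_size)
    index = [f"{c}:{s}-{e}" for c, s, e in bins]
    values = np.zeros(len(bins))
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for i, (chrom, bstart, bend) in enumerate(bins):
        w = wsum = 0.0
        for seg in by_chrom.get(chrom, []):
            olap = min(seg.end, bend) - max(seg.start, bstart)
            if olap > 0:
                w += olap
                wsum += olap * seg.log2_copy_ratio
        values[i] = wsum / w if w > 0 else 0.0
    return pd.Series(values, index=index)


def bin_matrix(
    segments_by_sample: dict[str, list[CNSegment]],
    annotation: GenomeAnnotation,
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Samples x bins matrix of binned CR profiles (fixed bin universe)."""
    samples = sorted(segments_by_sample)
    rows = [bin_profile(segments_by_sample[s], annotation, bin_size) for s in samples]
    return pd.DataFrame(rows, index=samples)


@dataclass
class CNClusterResult:
    linkage: np.ndarray
    chosen_k: int
    labels: pd.Series  # per sample, 1..chosen_k
    wss: dict[int, float]  # within-cluster sum of squares per k (incl. k=1)


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def cluster_cn_profiles(
    binned: pd.DataFrame,
    k_max: int = 8,
    method: str = "complete",
) -> CNClusterResult:
    """Hierarchical clustering of CN profiles with an elbow rule for k.

    Complete-linkage agglomeration on Euclidean distances. Within-cluster
    sum of squares (WSS) is computed for k = 1..k_max and the number of
    clusters is the k maximizing the second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1) over k in 2..k_max-1 (ties -> smaller
    k). Deterministic and invariant to sample order.
    """
    n = len(binned)
    if n < 3:
        raise ValueError("need >= 3 samples to cluster")
    if k_max >= n:
        raise ValueError("k_max must be < number of samples")
    X = binned.to_numpy(dtype=float)
    Z = linkage(X, method=method, metric="euclidean")
    wss = {1: _wss(X, np.zeros(n, dtype=int))}
    labels_by_k = {}
    for k in range(2, k_max + 1):
        labs = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = labs
        wss[k] = _wss(X, labs)
    best_k, best_gain = 2, -np.inf
    for k in range(2, k_max):
        gain = wss[k - 1] - 2 * wss[k] + wss[k + 1]
        if gain > best_gain + 1e-12:
            best_gain, best_k = gain, k
    labels = pd.Series(labels_by_k[best_k], index=binned.index, name="cn_cluster")
    return CNClusterResult(Z, best_k, labels, wss)
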