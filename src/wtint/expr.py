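"""Expression normalization, NMF subtyping, nz-score and Wnt-score statistics.

Counts are normalized with median-of-ratios size factors and a
log2(x + 1) transform — a monotone variance-stabilizing approximation of
the reference vst; an externally computed vst matrix can be supplied
instead wherever a NormalizedMatrix is accepted (``NormalizedMatrix.from_values``).

Expression profiles ("metagenes") are extracted by non-negative matrix
factorization with multiplicative updates. The factorization rank is
selected by consensus clustering over random restarts: for each candidate
k, samples are co-clustered by their dominant profile across n_runs
restarts, and the cophenetic correlation coefficient of the consensus
dissimilarity measures stability. The chosen k is the last one before the
coefficient first decreases.

The nz-score standardizes a tumor's expression of a gene against the
tumors that are copy-number neutral for that gene, so CN-driven expression
changes stand out. The Wnt score is the cohort-min-max-scaled mean
normalized expression over Wnt-pathway genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .annotation import GenomeAnnotation

_EPS = 1e-10


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x samples, vst scale
    size_factors: pd.Series | None = None

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "NormalizedMatrix":
        """Wrap an externally computed vst matrix (exact-parity hook)."""
        return cls(values=values, size_factors=None)


def vst_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Median-of-ratios normalization followed by log2(x + 1).

    Size factors follow the standard median-of-ratios estimator: the
    per-sample median of count ratios to the per-gene geometric mean,
    computed over genes expressed in every sample. Values are
    log2(count / size_factor + 1), strictly increasing in the raw count.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        # degenerate fixture: fall back to library-size factors
        sf = totals / totals.mean()
    else:
        logs = np.log(arr[positive])
        log_geomean = logs.mean(axis=1)
        sf_vals = np.exp(np.median(logs - log_geomean[:, None], axis=0))
        sf = pd.Series(sf_vals, index=counts.columns)
    values = np.log2(arr / sf.to_numpy()[None, :] + 1.0)
    return NormalizedMatrix(pd.DataFrame(values, index=counts.index, columns=counts.columns), sf)


def select_variable_genes(
    norm: NormalizedMatrix,
    annotation: GenomeAnnotation | None = None,
    n: int = 10_000,
    exclude_chroms: tuple[str, ...] = ("X", "Y", "MT"),
) -> list[str]:
    """Top-n genes by variance of normalized values.

    Genes on sex chromosomes / mitochondrial analogs are excluded first
    when an annotation is given. Ties break deterministically by gene id.
    """
    values = norm.values
    eligible = list(values.index)
    if annotation is not None:
        banned = {g.gene_id for g in annotation.genes if g.chrom in exclude_chroms}
        eligible = [g for g in eligible if g not in banned]
    variances = values.loc[eligible].var(axis=1, ddof=1)
    if n > len(eligible):
        warnings.warn(f"requested {n} variable genes but only {len(eligible)} eligible")
        n = len(eligible)
    order = sorted(eligible, key=lambda g: (-variances[g], g))
    return order[:n]


# ---- NMF with consensus rank selection ---------------------------------


@dataclass
class ExpressionProfiles:
    W: pd.DataFrame  # genes x k basis
    H: pd.DataFrame  # k x samples contributions
    k: int
    cophenetic: dict[int, float]
    consensus: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    reconstruction_error: float = float("nan")


def nmf_multiplicative(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One NMF run minimizing Frobenius error with multiplicative updates.

    Returns (W, H, error_trajectory); the trajectory is non-increasing up
    to floating-point noise, which property tests assert.
    """
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS
    errors: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(V - W @ H))
        errors.append(err)
        if prev - err < tol * max(prev, 1.0):
            break
        prev = err
    return W, H, errors


def _consensus_matrix(label_runs: list[np.ndarray]) -> np.ndarray:
    m = label_runs[0].shape[0]
    C = np.zeros((m, m))
    for labs in label_runs:
        C += labs[:, None] == labs[None, :]
    return C / len(label_runs)


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    cond = squareform(D, checks=False)
    if np.allclose(cond, cond[0] if cond.size else 0.0):
        # all pairs equally (dis)similar: perfectly stable if fully
        # co-clustered, maximally unstable otherwise
        return 1.0 if (cond.size == 0 or np.allclose(cond, 0.0)) else 0.0
    Z = linkage(cond, method="average")
    c, _ = cophenet(Z, cond)
    return float(c)


def nmf_rank_and_factorize(
    matrix: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 300,
) -> ExpressionProfiles:
    """Consensus NMF over a range of ranks with cophenetic rank selection.

    For each k, ``n_runs`` seeded multiplicative-update factorizations are
    run from random initializations; samples are assigned to their argmax
    profile and the run-averaged co-clustering matrix gives the consensus.
    The chosen rank is the last k (in ascending order) before the
    cophenetic coefficient first strictly decreases; the returned W/H are
    the best-reconstruction run at that rank.
    """
    ks = sorted(set(k_range))
    if not ks:
        raise ValueError("empty k_range")
    V = matrix.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    n_samples = V.shape[1]
    if ks[-1] > max(1, n_samples - 1):
        raise ValueError("k_range exceeds n_samples - 1")
    root = np.random.default_rng(seed)
    run_seeds = root.integers(0, 2**31 - 1, size=(len(ks), n_runs))
    coph: dict[int, float] = {}
    consensus: dict[int, np.ndarray] = {}
    best: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    for ki, k in enumerate(ks):
        label_runs = []
        for r in range(n_runs):
            rng = np.random.default_rng(int(run_seeds[ki, r]))
            W, H, errs = nmf_multiplicative(V, k, rng, max_iter=max_iter)
            label_runs.append(np.argmax(H, axis=0))
            if k not in best or errs[-1] < best[k][0]:
                best[k] = (errs[-1], W, H)
        C = _consensus_matrix(label_runs)
        consensus[k] = C
        coph[k] = _cophenetic_coefficient(C)
    chosen = ks[-1]
    for a, b in zip(ks, ks[1:]):
        if coph[b] < coph[a]:
            chosen = a
            break
    err, W, H = best[chosen]
    Wdf = pd.DataFrame(W, index=matrix.index, columns=[f"P{i+1}" for i in range(chosen)])
    Hdf = pd.DataFrame(H, index=[f"P{i+1}" for i in range(chosen)], columns=matrix.columns)
    return ExpressionProfiles(Wdf, Hdf, chosen, coph, consensus, err)


def assign_clusters(H: pd.DataFrame) -> pd.Series:
    """Per-sample cluster = argmax of column-normalized profile contributions.

    Ties break to the lowest profile index with a warning.
    """
    if (H.sum(axis=0) == 0).any():
        raise ValueError("all-zero contribution column")
    rel = H / H.sum(axis=0)
    arr = rel.to_numpy()
    idx = arr.argmax(axis=0)
    for j in range(arr.shape[1]):
        if (arr[:, j] == arr[idx[j], j]).sum() > 1:
            warnings.warn(f"tied profile contributions for sample {H.columns[j]}")
    return pd.Series(idx + 1, index=H.columns, name="expression_cluster")


def assign_genes_to_profiles(
    W: pd.DataFrame,
    cluster_labels: pd.Series,
    norm: NormalizedMatrix,
    top_n: int = 1000,
) -> tuple[pd.Series, dict[int, list[str]]]:
    """Assign genes to their max-weight profile and rank by log2 fold change.

    Within each profile, genes are ranked by l2fc = mean vst in the
    profile's cluster minus mean vst outside it; the top_n per profile are
    returned (whole profile with a warning if smaller).
    """
    arr = W.to_numpy()
    prof_idx = arr.argmax(axis=1)
    for i in range(arr.shape[0]):
        if (arr[i] == arr[i, prof_idx[i]]).sum() > 1:
            warnings.warn(f"tied basis weights for gene {W.index[i]}")
    gene_profile = pd.Series(prof_idx + 1, index=W.index, name="profile")
    values = norm.values
    top: dict[int, list[str]] = {}
    for p in range(1, W.shape[1] + 1):
        in_cluster = cluster_labels.index[cluster_labels == p]
        out_cluster = cluster_labels.index[cluster_labels != p]
        members = [g for g in W.index if gene_profile[g] == p]
        if not in_cluster.size or not out_cluster.size:
            top[p] = members[:top_n]
            continue
        l2fc = values.loc[members, in_cluster].mean(axis=1) - values.loc[members, out_cluster].mean(axis=1)
        ranked = sorted(members, key=lambda g: (-l2fc[g], g))
        if top_n > len(ranked):
            warnings.warn(f"profile {p} has only {len(ranked)} genes (< top_n)")
        top[p] = ranked[:top_n]
    return gene_profile, top


# ---- CN-referenced statistics ------------------------------------------


@dataclass
class NZScoreTable:
    nz: pd.DataFrame  # genes x samples
    n_neutral: pd.Series
    mean_neutral: pd.Series
    sd_neutral: pd.Series
    undefined_genes: list[str]


def nz_score(norm: NormalizedMatrix, gene_cn_status: pd.DataFrame) -> NZScoreTable:
    """z-score of vst values against the per-gene CN-neutral tumor set.

    nz = (vst - mean_neutral) / sd_neutral with the sample (n-1) standard
    deviation; undefined (NaN, flagged) when fewer than two neutral tumors
    exist or their sd is zero. Genes absent from the CN data are flagged.
    """
    values = norm.values
    common = [s for s in values.columns if s in gene_cn_status.columns]
    nz = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    n_neutral = pd.Series(0, index=values.index, dtype=int)
    mean_neutral = pd.Series(np.nan, index=values.index)
    sd_neutral = pd.Series(np.nan, index=values.index)
    undefined: list[str] = []
    for gene in values.index:
        if gene not in gene_cn_status.index:
            undefined.append(gene)
            continue
        status = gene_cn_status.loc[gene, common]
        neutral = [s for s in common if status[s] == "neutral"]
        n_neutral[gene] = len(neutral)
        if len(neutral) < 2:
            undefined.append(gene)
            continue
        ref = values.loc[gene, neutral].to_numpy(dtype=float)
        mu, sd = float(ref.mean()), float(ref.std(ddof=1))
        mean_neutral[gene], sd_neutral[gene] = mu, sd
        if sd == 0:
            undefined.append(gene)
            continue
        nz.loc[gene] = (values.loc[gene] - mu) / sd
    return NZScoreTable(nz, n_neutral, mean_neutral, sd_neutral, undefined)


@dataclass
class WntScore:
    raw_mean: pd.Series  # per-tumor mean vst over Wnt genes
    score: pd.Series  # min-max scaled to [0, 1]


def wnt_score(norm: NormalizedMatrix, wnt_gene_set: list[str]) -> WntScore:
    """Cohort-scaled Wnt-pathway activation score per tumor."""
    genes = [g for g in wnt_gene_set if g in norm.values.index]
    if not genes:
        raise ValueError("no Wnt genes present in the expression matrix")
    if norm.values.shape[1] < 2:
        raise ValueError("need >= 2 tumors")
    raw = norm.values.loc[genes].mean(axis=0)
    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn("constant Wnt means across tumors; scores set to 0")
        score = pd.Series(0.0, index=raw.index)
    else:
        score = (raw - raw.min()) / span
    return WntScore(raw, score.rename("wnt_score"))
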