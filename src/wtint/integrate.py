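"""CN/SV-expression integration: dosage tests, co-occurrence funnel, labels.

Three analyses link the DNA and RNA layers:

* ``cn_expression_test`` — for genes recurrently gained or lost (>= 3
  tumors), a Wilcoxon rank-sum test of vst expression in altered vs
  CN-neutral tumors, BH-adjusted (FDR < 0.2) with a minimum log2
  fold-change of log2(1.10) ~ 0.138 (a 10% change);
* ``cooccurrence_funnel`` — per expression cluster, genes recurrently
  upregulated (nz > 1.5 in >= 2 cluster tumors) narrowed to those whose
  upregulation co-occurs with a gene-body gain or an SV breakpoint within
  1 Mbp, in >= 1 and then >= 2 tumors;
* ``label_gene_alterations`` — per gene x tumor evidence labels
  {snv, sv_bp, sv_indirect, gain, loss} and the simplified {snv, sv, cna},
  where indirect evidence (spanning/nearby SV, CN gain/loss) additionally
  requires an expression change |nz| > 1.98.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .expr import NZScoreTable
from .snv import SmallVariant
from .sv import MergedSV

#: minimum |log2 fold change| for a biologically relevant shift (10% change)
L2FC_THRESHOLD = round(math.log2(1.10), 3)  # 0.138
FDR_THRESHOLD = 0.2
NZ_UPREGULATED = 1.5
NZ_CHANGED = 1.98
SV_WINDOW = 1_000_000


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled size is <= 10 with no ties; normal
    approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 10 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEGResult:
    gene: str
    direction: str  # gain | loss
    n_altered: int
    l2fc: float
    p_value: float
    q_value: float
    significant: bool


def cn_expression_test(
    norm,
    gene_cn_status: pd.DataFrame,
    min_recurrence: int = 3,
    fdr: float = FDR_THRESHOLD,
    min_l2fc: float = L2FC_THRESHOLD,
) -> list[DEGResult]:
    """Test recurrently CN-altered genes for expression differences.

    Gains and losses are assessed separately; a gene/direction is tested
    when >= ``min_recurrence`` tumors carry the alteration and >= 2 tumors
    are CN-neutral for the gene. l2fc is the difference of mean vst values
    (altered - neutral). BH adjustment is applied jointly across all tests;
    significance requires q < ``fdr`` and |l2fc| > ``min_l2fc``.
    """
    values = norm.values
    samples = [s for s in values.columns if s in gene_cn_status.columns]
    rows: list[tuple[str, str, int, float, float]] = []
    for gene in values.index:
        if gene not in gene_cn_status.index:
            continue
        status = gene_cn_status.loc[gene, samples]
        neutral = [s for s in samples if status[s] == "neutral"]
        if len(neutral) < 2:
            continue
        for direction in ("gain", "loss"):
            altered = [s for s in samples if status[s] == direction]
            if len(altered) < min_recurrence:
                continue
            xv = values.loc[gene, altered].to_numpy(dtype=float)
            yv = values.loc[gene, neutral].to_numpy(dtype=float)
            p = wilcoxon_rank_sum(xv, yv)
            l2fc = float(xv.mean() - yv.mean())
            rows.append((gene, direction, len(altered), l2fc, p))
    if not rows:
        return []
    q = bh_adjust([r[4] for r in rows])
    return [
        DEGResult(g, d, n, l2fc, p, float(qv), bool(qv < fdr and abs(l2fc) > min_l2fc))
        for (g, d, n, l2fc, p), qv in zip(rows, q)
    ]


# ---- co-occurrence funnel ----------------------------------------------


@dataclass
class FunnelResult:
    cluster: int
    recurrently_upregulated: set[str]
    upregulated_with_cnsv_any_tumor: set[str]
    upregulated_with_recurrent_cnsv: set[str]
    expressed_with_recurrent_cnsv: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "recurrently_upregulated": len(self.recurrently_upregulated),
            "upregulated_with_cnsv_any_tumor": len(self.upregulated_with_cnsv_any_tumor),
            "upregulated_with_recurrent_cnsv": len(self.upregulated_with_recurrent_cnsv),
            "expressed_with_recurrent_cnsv": len(self.expressed_with_recurrent_cnsv),
        }


def _breakpoints_by_chrom(svs: list[MergedSV]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for sv in svs:
        for chrom, pos in sv.breakpoints():
            out.setdefault(chrom, []).append(pos)
    return out


def _gene_has_nearby_breakpoint(gene, bps: dict[str, list[int]], window: int) -> bool:
    return any(gene.start - window <= p <= gene.end + window for p in bps.get(gene.chrom, []))


def cooccurrence_funnel(
    cluster_labels: pd.Series,
    nz_table: NZScoreTable,
    gene_cn_status: pd.DataFrame,
    merged_svs_by_sample: dict[str, list[MergedSV]],
    annotation: GenomeAnnotation,
    norm=None,
    nz_threshold: float = NZ_UPREGULATED,
    window: int = SV_WINDOW,
    min_recurrence: int = 2,
    min_expressed_vst: float = 1.0,
) -> list[FunnelResult]:
    """Per-cluster funnel of upregulation co-occurring with CN gains / SVs.

    Only upregulation is considered (profiles are non-negative components).
    A gene is "CN/SV altered" in a tumor when its gene body is called a
    gain or any SV breakpoint of that tumor lies within ``window`` bp of
    the gene span (inclusive). Tumors present in the expression data but
    absent from the DNA data are excluded with a warning. The last stage is
    the reference set: all expressed genes (cohort mean vst >=
    ``min_expressed_vst``) carrying a recurrent CN/SV in the cluster.
    """
    import warnings as _warnings

    nz = nz_table.nz
    genes_by_id = {g.gene_id: g for g in annotation.genes}
    usable = []
    for sample in cluster_labels.index:
        if sample in gene_cn_status.columns and sample in merged_svs_by_sample:
            usable.append(sample)
        else:
            _warnings.warn(f"sample {sample} lacks DNA data; excluded from funnel")
    bps = {s: _breakpoints_by_chrom(merged_svs_by_sample[s]) for s in usable}
    if norm is not None:
        expressed = set(norm.values.index[norm.values.mean(axis=1) >= min_expressed_vst])
    else:
        expressed = set(nz.index)

    results = []
    for cluster in sorted(cluster_labels.unique()):
        members = [s for s in usable if cluster_labels[s] == cluster]

        def altered(gene_id: str, sample: str) -> bool:
            gain = (
                gene_id in gene_cn_status.index
                and gene_cn_status.loc[gene_id, sample] == "gain"
            )
            if gain:
                return True
            gene = genes_by_id.get(gene_id)
            return gene is not None and _gene_has_nearby_breakpoint(gene, bps[sample], window)

        stage1: set[str] = set()
        stage2: set[str] = set()
        stage3: set[str] = set()
        for gene_id in nz.index:
            up = [s for s in members if s in nz.columns and nz.loc[gene_id, s] > nz_threshold]
            if len(up) < min_recurrence:
                continue
            stage1.add(gene_id)
            co = [s for s in up if altered(gene_id, s)]
            if len(co) >= 1:
                stage2.add(gene_id)
            if len(co) >= min_recurrence:
                stage3.add(gene_id)

        reference: set[str] = set()
        for gene_id in nz.index:
            if gene_id not in expressed:
                continue
            n_hit = sum(1 for s in members if altered(gene_id, s))
            if n_hit >= min_recurrence:
                reference.add(gene_id)
        results.append(FunnelResult(int(cluster), stage1, stage2, stage3, reference))
    return results


# ---- gene-level alteration labels --------------------------------------

SIMPLE_MAP = {"snv": "snv", "sv_bp": "sv", "sv_indirect": "sv", "gain": "cna", "loss": "cna"}


@dataclass(frozen=True)
class AlterationRecord:
    gene: str
    tumor: str
    labels: frozenset[str]
    simple_labels: frozenset[str]
    nz: float | None
    evidence: tuple[str, ...]


def label_gene_alterations(
    variants_by_sample: dict[str, list[SmallVariant]],
    merged_svs_by_sample: dict[str, list[MergedSV]],
    gene_cn_status: pd.DataFrame,
    nz_table: NZScoreTable | None,
    annotation: GenomeAnnotation,
    nz_changed: float = NZ_CHANGED,
    window: int = SV_WINDOW,
    genes: list[str] | None = None,
) -> list[AlterationRecord]:
    """Combine SNV, SV and CN evidence into per-gene-per-tumor labels.

    Direct evidence needs no expression support: a non-benign SNV/indel in
    the gene body (benign SIFT/PolyPhen predictions are dropped unless the
    variant is in COSMIC), or an SV breakpoint inside the gene body
    (sv_bp). Indirect evidence — an SV spanning the gene or a breakpoint
    within ``window`` bp (sv_indirect), or a gene-body CN gain/loss —
    additionally requires |nz| > ``nz_changed``. Tumors without RNA data
    can only receive direct labels.
    """
    gene_objs = annotation.genes if genes is None else [annotation.gene(g) for g in genes]
    samples = sorted(set(variants_by_sample) | set(merged_svs_by_sample))
    records: list[AlterationRecord] = []
    for sample in samples:
        variants = variants_by_sample.get(sample, [])
        svs = merged_svs_by_sample.get(sample, [])
        for gene in gene_objs:
            labels: set[str] = set()
            evidence: list[str] = []
            nz_val: float | None = None
            if nz_table is not None and sample in nz_table.nz.columns and gene.gene_id in nz_table.nz.index:
                raw = nz_table.nz.loc[gene.gene_id, sample]
                nz_val = None if pd.isna(raw) else float(raw)

            for v in variants:
                if v.chrom == gene.chrom and gene.start <= v.pos - 1 < gene.end:
                    if v.sift_polyphen_benign and not v.in_cosmic:
                        continue
                    labels.add("snv")
                    evidence.append(f"snv:{v.chrom}:{v.pos}:{v.ref}>{v.alt}")

            has_bp_inside = False
            has_indirect_sv = False
            for sv in svs:
                inside = [
                    (c, p) for c, p in sv.breakpoints() if c == gene.chrom and gene.start <= p < gene.end
                ]
                if inside:
                    has_bp_inside = True
                    evidence.append(f"sv_bp:{sv.svtype}:{inside[0][0]}:{inside[0][1]}")
                spanning = (
                    sv.svtype in ("DEL", "DUP", "INV")
                    and sv.chrom == gene.chrom
                    and sv.start <= gene.start
                    and sv.end >= gene.end
                )
                nearby = any(
                    c == gene.chrom and gene.start - window <= p <= gene.end + window
                    for c, p in sv.breakpoints()
                )
                if spanning or nearby:
                    has_indirect_sv = True
            if has_bp_inside:
                labels.add("sv_bp")

            expressed_change = nz_val is not None and abs(nz_val) > nz_changed
            if has_indirect_sv and expressed_change:
                labels.add("sv_indirect")
                evidence.append(f"sv_indirect:nz={nz_val:.2f}")
            if gene.gene_id in gene_cn_status.index and sample in gene_cn_status.columns:
                call = gene_cn_status.loc[gene.gene_id, sample]
                if call in ("gain", "loss") and expressed_change:
                    labels.add(call)
                    evidence.append(f"{call}:nz={nz_val:.2f}")

            if labels:
                simple = frozenset(SIMPLE_MAP[lab] for lab in labels)
                records.append(
                    AlterationRecord(gene.gene_id, sample, frozenset(labels), simple, nz_val, tuple(evidence))
                )
    return records


def alteration_table(records: list[AlterationRecord]) -> pd.DataFrame:
    """Long-format gene x tumor alteration table (oncoplot-ready)."""
    rows = [
        {
            "gene": r.gene,
            "tumor": r.tumor,
            "alteration": " ".join(sorted(r.labels)),
            "alteration_simple": " ".join(sorted(r.simple_labels)),
            "nz": r.nz,
        }
        for r in sorted(records, key=lambda r: (r.gene, r.tumor))
    ]
    return pd.DataFrame(rows, columns=["gene", "tumor", "alteration", "alteration_simple", "nz"])
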