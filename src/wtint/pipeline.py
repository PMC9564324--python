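"""End-to-end orchestration: config validation, stage running, manifest.

The pipeline consumes a cohort directory (annotation, per-caller SV VCFs,
CN segment TSV, SNV TSV, expression counts TSV, population-SV VCF) plus a
YAML/JSON configuration of thresholds, and writes per-stage result tables
under the output directory:

    results/sv/           consensus SVs per sample (VCF)
    results/snv/          high-confidence variants, burden, signature input
    results/cn/           arm/gene summaries, binned matrix, CN clusters
    results/expr/         vst matrix, W/H, clusters, nz table, Wnt score
    results/integration/  DEG table, funnel JSON, alteration labels
    results/1q/           shared region, clonality, mechanism calls

Reruns with the same config and seed are byte-identical; the manifest
records a config hash and per-output checksums to make this auditable.
Samples without RNA flow through the DNA stages and are skipped by the
expression-dependent ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chr1q, cn, expr, integrate, snv as snv_mod, sv as sv_mod
from .annotation import read_annotation
from .cn import CNSegment
from .snv import SmallVariant
from .vcfio import read_sv_vcf, write_sv_vcf

DEFAULT_THRESHOLDS = {
    "min_reads": 7,
    "ro_pop": 0.9,
    "ro_merge": 0.5,
    "min_callers": 2,
    "min_af": 0.1,
    "cr_threshold": 0.2,
    "fdr": 0.2,
    "min_l2fc": integrate.L2FC_THRESHOLD,
    "nz_upregulated": 1.5,
    "nz_changed": 1.98,
    "sv_window_bp": 1_000_000,
    "boundary_tol_bp": 10_000,
    "min_recurrence": 3,
}

_FRACTIONAL = {"ro_pop", "ro_merge", "min_af", "fdr"}


@dataclass
class PipelineConfig:
    cohort_dir: Path
    outdir: Path
    seed: int = 0
    thresholds: dict = field(default_factory=dict)
    nmf_k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    nmf_runs: int = 30
    n_variable_genes: int = 200
    purity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        self.cohort_dir = Path(self.cohort_dir)
        self.outdir = Path(self.outdir)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            cohort_dir=raw["cohort_dir"],
            outdir=raw.get("outdir", "results"),
            seed=int(raw.get("seed", 0)),
            thresholds=raw.get("thresholds", {}),
            nmf_k_range=tuple(raw.get("nmf_k_range", (2, 3, 4, 5, 6))),
            nmf_runs=int(raw.get("nmf_runs", 30)),
            n_variable_genes=int(raw.get("n_variable_genes", 200)),
            purity={k: float(v) for k, v in raw.get("purity", {}).items()},
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return an aggregated list of configuration errors (empty if valid)."""
    errors: list[str] = []
    d = config.cohort_dir
    for required in ("annotation", "cn_segments.tsv", "snvs.tsv", "popdb.vcf", "sv"):
        if not (d / required).exists():
            errors.append(f"missing input: {d / required}")
    for key, value in config.thresholds.items():
        if key in _FRACTIONAL and not 0.0 <= float(value) <= 1.0:
            errors.append(f"threshold {key}={value} outside [0, 1]")
        elif key not in _FRACTIONAL and float(value) < 0:
            errors.append(f"threshold {key}={value} must be non-negative")
    for sample, p in config.purity.items():
        if not 0.0 < p <= 1.0:
            errors.append(f"purity[{sample}]={p} outside (0, 1]")
    counts_path = d / "counts.tsv"
    if counts_path.exists() and not errors:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, nrows=1)
        segs = pd.read_csv(d / "cn_segments.tsv", sep="\t", usecols=["sample"])
        dna_samples = set(segs["sample"].unique())
        for s in counts.columns:
            if s not in dna_samples:
                errors.append(f"sample {s} has counts but no CN segments (nz reference undefined)")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort_dir(config: PipelineConfig):
    d = config.cohort_dir
    annotation = read_annotation(d / "annotation")
    seg_df = pd.read_csv(d / "cn_segments.tsv", sep="\t")
    segments: dict[str, list[CNSegment]] = {}
    for row in seg_df.itertuples(index=False):
        maf = None if pd.isna(row.minor_allele_fraction) else float(row.minor_allele_fraction)
        segments.setdefault(row.sample, []).append(
            CNSegment(row.sample, str(row.chrom), int(row.start), int(row.end),
                      float(row.log2_copy_ratio), maf, int(row.n_points))
        )
    for sample in segments:
        segments[sample].sort(key=lambda s: (s.chrom, s.start))

    callsets: dict[str, dict[str, list]] = {}
    for vcf_path in sorted((d / "sv").glob("*.vcf")):
        sample, caller = vcf_path.stem.split(".", 1)
        callsets.setdefault(sample, {})[caller] = read_sv_vcf(vcf_path, default_caller=caller)
    popdb = read_sv_vcf(d / "popdb.vcf", default_caller="popdb")

    snv_df = pd.read_csv(d / "snvs.tsv", sep="\t")
    variants: dict[str, list[SmallVariant]] = {}
    for row in snv_df.itertuples(index=False):
        variants.setdefault(row.sample, []).append(
            SmallVariant(
                row.sample, str(row.chrom), int(row.pos), row.ref, row.alt,
                (None if pd.isna(row.gene_id) or row.gene_id == "" else str(row.gene_id)),
                float(row.tumor_af), int(row.tumor_depth), int(row.normal_depth),
                int(row.normal_alt_reads), row.impact,
                bool(row.sift_polyphen_benign), bool(row.in_dbsnp), bool(row.in_cosmic),
            )
        )

    counts = None
    if (d / "counts.tsv").exists():
        counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    return annotation, segments, callsets, popdb, variants, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    th = config.thresholds
    out = config.outdir
    annotation, segments, callsets, popdb, variants, counts = _load_cohort_dir(config)
    samples = sorted(segments)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps({**th, "seed": config.seed, "nmf_k_range": list(config.nmf_k_range),
                        "nmf_runs": config.nmf_runs}, sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "checksums": {},
        "samples": {s: {"has_rna": bool(counts is not None and s in counts.columns)}
                    for s in samples},
    }

    # --- SV consensus ---------------------------------------------------
    svdir = out / "sv"
    svdir.mkdir(parents=True, exist_ok=True)
    merged_by_sample: dict[str, list] = {}
    for sample in samples:
        sets = callsets.get(sample, {})
        if len(sets) < int(th["min_callers"]):
            merged_by_sample[sample] = []
            continue
        merged = sv_mod.consensus_pipeline(
            sets, popdb, min_reads=int(th["min_reads"]), ro_pop=th["ro_pop"],
            ro_merge=th["ro_merge"], min_callers=int(th["min_callers"]),
            min_af=th["min_af"],
        )
        merged_by_sample[sample] = merged
        calls = [
            sv_mod.SVCall(f"cons_{i}", "+".join(sorted(m.callers)), m.svtype, m.chrom,
                          m.start, m.end, 0, m.allele_fraction, m.inverted,
                          m.chrom2, m.pos2, m.orient1, m.orient2)
            for i, m in enumerate(merged)
        ]
        write_sv_vcf(calls, svdir / f"{sample}.consensus.vcf", annotation)
    manifest["stages"].append("sv_consensus")

    # --- small variants -------------------------------------------------
    snvdir = out / "snv"
    snvdir.mkdir(parents=True, exist_ok=True)
    hc: dict[str, list[SmallVariant]] = {
        s: snv_mod.filter_high_confidence(variants.get(s, [])) for s in samples
    }
    burden_rows = []
    for s in samples:
        b = snv_mod.mutation_burden(hc[s], annotation)
        burden_rows.append([s, b.n_nonsynonymous, b.denominator_mbp, b.burden_per_mbp])
    pd.DataFrame(burden_rows, columns=["sample", "n_nonsynonymous", "denominator_mbp",
                                       "burden_per_mbp"]).to_csv(
        snvdir / "burden.tsv", sep="\t", index=False)
    sig_sets, sig_excluded = snv_mod.signature_input_filter(hc)
    pd.DataFrame(
        [[s, len(v), s in sig_excluded] for s, v in sorted(sig_sets.items())],
        columns=["sample", "n_signature_snvs", "excluded_from_signatures"],
    ).to_csv(snvdir / "signature_input.tsv", sep="\t", index=False)
    manifest["stages"].append("small_variants")

    # --- CN profiles ----------------------------------------------------
    cndir = out / "cn"
    cndir.mkdir(parents=True, exist_ok=True)
    crth = float(th["cr_threshold"])
    arm_rows = []
    arm_summaries = {}
    for s in samples:
        summ = cn.summarize_arms(segments[s], annotation, crth)
        arm_summaries[s] = summ
        for arm_name, a in sorted(summ.items()):
            arm_rows.append([s, arm_name, a.weighted_cr, a.weighted_maf,
                             a.covered_fraction, a.call])
    pd.DataFrame(arm_rows, columns=["sample", "arm", "weighted_cr", "weighted_maf",
                                    "covered_fraction", "call"]).to_csv(
        cndir / "arm_summary.tsv", sep="\t", index=False)
    status = cn.gene_cn_status(segments, annotation, crth)
    status.to_csv(cndir / "gene_cn_status.tsv", sep="\t")
    gaf = pd.Series({s: cn.genome_altered_fraction(segments[s], annotation, crth)
                     for s in samples}, name="genome_altered_fraction")
    gaf.to_csv(cndir / "genome_altered_fraction.tsv", sep="\t")
    binned = cn.bin_matrix(segments, annotation)
    binned.to_csv(cndir / "binned_profiles.tsv", sep="\t")
    if len(samples) >= 4:
        cn_clusters = cn.cluster_cn_profiles(binned, k_max=min(8, len(samples) - 1))
        cn_clusters.labels.to_csv(cndir / "cn_clusters.tsv", sep="\t")
        manifest["cn_chosen_k"] = cn_clusters.chosen_k
    manifest["stages"].append("cn_profiles")

    # --- expression -----------------------------------------------------
    nz_table = None
    norm = None
    cluster_labels = None
    if counts is not None and counts.shape[1] >= 3:
        exdir = out / "expr"
        exdir.mkdir(parents=True, exist_ok=True)
        norm = expr.vst_normalize(counts)
        norm.values.to_csv(exdir / "vst.tsv", sep="\t")
        variable = expr.select_variable_genes(norm, annotation, n=config.n_variable_genes)
        k_range = tuple(k for k in config.nmf_k_range if k <= counts.shape[1] - 1)
        profiles = expr.nmf_rank_and_factorize(
            norm.values.loc[variable], k_range=k_range, n_runs=config.nmf_runs,
            seed=config.seed,
        )
        profiles.W.to_csv(exdir / "nmf_W.tsv", sep="\t")
        profiles.H.to_csv(exdir / "nmf_H.tsv", sep="\t")
        pd.Series(profiles.cophenetic, name="cophenetic").rename_axis("k").to_csv(
            exdir / "cophenetic.tsv", sep="\t")
        cluster_labels = expr.assign_clusters(profiles.H)
        cluster_labels.to_csv(exdir / "expression_clusters.tsv", sep="\t")
        manifest["expression_chosen_k"] = profiles.k
        nz_table = expr.nz_score(norm, status)
        nz_long = nz_table.nz.stack().rename("nz").rename_axis(["gene", "tumor"]).reset_index()
        nz_long.to_csv(exdir / "nz_scores.tsv", sep="\t", index=False)
        wnt_genes = annotation.gene_sets.get("WNT_SIGNALING", [])
        if wnt_genes:
            ws = expr.wnt_score(norm, wnt_genes)
            pd.DataFrame({"raw_mean": ws.raw_mean, "wnt_score": ws.score}).to_csv(
                exdir / "wnt_score.tsv", sep="\t")
        manifest["stages"].append("expression")

    # --- integration ----------------------------------------------------
    intdir = out / "integration"
    intdir.mkdir(parents=True, exist_ok=True)
    if norm is not None and nz_table is not None:
        degs = integrate.cn_expression_test(
            norm, status, min_recurrence=int(th["min_recurrence"]),
            fdr=th["fdr"], min_l2fc=th["min_l2fc"],
        )
        pd.DataFrame([vars(d) for d in degs]).to_csv(intdir / "deg.tsv", sep="\t", index=False)
        funnel = integrate.cooccurrence_funnel(
            cluster_labels, nz_table, status, merged_by_sample, annotation, norm=norm,
            nz_threshold=th["nz_upregulated"], window=int(th["sv_window_bp"]),
        )
        funnel_json = {
            str(f.cluster): {**f.counts, "stage_genes": {
                "recurrently_upregulated": sorted(f.recurrently_upregulated),
                "upregulated_with_cnsv_any_tumor": sorted(f.upregulated_with_cnsv_any_tumor),
                "upregulated_with_recurrent_cnsv": sorted(f.upregulated_with_recurrent_cnsv),
                "expressed_with_recurrent_cnsv": sorted(f.expressed_with_recurrent_cnsv),
            }} for f in funnel
        }
        (intdir / "funnel.json").write_text(json.dumps(funnel_json, indent=1, sort_keys=True))
    records = integrate.label_gene_alterations(
        hc, merged_by_sample, status, nz_table, annotation,
        nz_changed=th["nz_changed"], window=int(th["sv_window_bp"]),
    )
    integrate.alteration_table(records).to_csv(intdir / "alterations.tsv", sep="\t", index=False)
    manifest["stages"].append("integration")

    # --- 1q mechanisms --------------------------------------------------
    qdir = out / "1q"
    qdir.mkdir(parents=True, exist_ok=True)
    q_arm = annotation.arm("1q")
    gained_by_tumor = {}
    mech_rows = []
    clon_rows = []
    for s in samples:
        q_summary = arm_summaries[s]["1q"]
        gains = chr1q.gained_intervals(segments[s], (q_arm.chrom, q_arm.start, q_arm.end), crth)
        if q_summary.call != "gain" and not gains:
            continue
        gained_by_tumor[s] = gains
        purity = config.purity.get(s, 1.0)
        est = chr1q.infer_clonality(
            q_summary.weighted_cr, q_summary.weighted_maf, purity,
            covered_fraction=q_summary.covered_fraction,
        )
        clon_rows.append([s, est.observed_cr, est.observed_maf, est.expected_cr,
                          est.expected_maf, est.verdict, est.extra_copies])
        call = chr1q.classify_1q_mechanism(
            s, segments[s], annotation, merged_by_sample.get(s, []),
            boundary_tol=int(th["boundary_tol_bp"]), threshold=crth,
        )
        mech_rows.append([s, call.mechanism, call.independent_focal_p_loss,
                          "; ".join(call.evidence)])
    if gained_by_tumor:
        shared = chr1q.shared_gained_region(gained_by_tumor)
        with open(qdir / "shared_region.bed", "w") as fh:
            for s_, e_ in shared:
                fh.write(f"1\t{s_}\t{e_}\tshared_1q_gain\n")
    pd.DataFrame(clon_rows, columns=["sample", "observed_cr", "observed_maf", "expected_cr",
                                     "expected_maf", "verdict", "extra_copies"]).to_csv(
        qdir / "clonality.tsv", sep="\t", index=False)
    pd.DataFrame(mech_rows, columns=["sample", "mechanism", "independent_focal_1p_loss",
                                     "evidence"]).to_csv(
        qdir / "mechanisms.tsv", sep="\t", index=False)
    manifest["stages"].append("chr1q_mechanisms")

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
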