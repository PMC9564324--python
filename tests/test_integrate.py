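import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wtint.annotation import Arm, Gene, GenomeAnnotation
from wtint.expr import NormalizedMatrix, NZScoreTable, nz_score
from wtint.integrate import (
    L2FC_THRESHOLD,
    alteration_table,
    bh_adjust,
    cn_expression_test,
    cooccurrence_funnel,
    label_gene_alterations,
    wilcoxon_rank_sum,
)
from wtint.snv import SmallVariant
from wtint.sv import MergedSV


def exact_wilcoxon_oracle(x, y):
    """Enumerate all assignments of pooled ranks to group x (no ties)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    all_ranks = list(range(1, len(pooled) + 1))
    stats = [sum(c) for c in itertools.combinations(all_ranks, n)]
    mean_w = n * (len(pooled) + 1) / 2
    extreme = sum(1 for s in stats if abs(s - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(stats)


class TestWilcoxon:
    def test_printed_exact_case(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_cases(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(2, 6 - max(0, n - 3)))
            vals = rng.choice(np.arange(1000), size=n + m, replace=False).astype(float)
            x, y = vals[:n], vals[n:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_wilcoxon_oracle(x, y), abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCnExpressionTest:
    def _norm_status(self, rng, n_altered=10, n_neutral=10, effect=0.0):
        samples = [f"a{i}" for i in range(n_altered)] + [f"n{i}" for i in range(n_neutral)]
        vals = rng.normal(5, 0.3, size=(1, len(samples)))
        vals[0, :n_altered] += effect
        values = pd.DataFrame(vals, index=["g"], columns=samples)
        status = pd.DataFrame(
            [["gain"] * n_altered + ["neutral"] * n_neutral], index=["g"], columns=samples
        )
        return NormalizedMatrix.from_values(values), status

    def test_planted_dosage_effect_detected(self, rng):
        # ~1.4-fold dosage on log2 scale is a shift of log2(1.4) = 0.485
        norm, status = self._norm_status(rng, effect=math.log2(1.4))
        res = cn_expression_test(norm, status)
        assert len(res) == 1
        assert res[0].significant and res[0].l2fc > L2FC_THRESHOLD

    def test_insufficient_recurrence_not_tested(self, rng):
        norm, status = self._norm_status(rng, n_altered=2, effect=2.0)
        assert cn_expression_test(norm, status) == []

    def test_identical_distributions_not_significant(self):
        samples = [f"a{i}" for i in range(5)] + [f"n{i}" for i in range(5)]
        values = pd.DataFrame([[1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]], index=["g"], columns=samples)
        status = pd.DataFrame([["gain"] * 5 + ["neutral"] * 5], index=["g"], columns=samples)
        res = cn_expression_test(NormalizedMatrix.from_values(values), status)
        assert res and not res[0].significant
        assert res[0].l2fc == pytest.approx(0.0)

    def test_null_fdr_control_over_replicates(self):
        # at zero planted effect the q < 0.2 rule rarely fires
        n_sig = n_tests = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"a{i}" for i in range(5)] + [f"n{i}" for i in range(8)]
            values = pd.DataFrame(rng.normal(5, 0.5, size=(30, 13)),
                                  index=[f"g{i}" for i in range(30)], columns=samples)
            status = pd.DataFrame([["gain"] * 5 + ["neutral"] * 8] * 30,
                                  index=values.index, columns=samples)
            res = cn_expression_test(NormalizedMatrix.from_values(values), status)
            n_tests += len(res)
            n_sig += sum(r.significant for r in res)
        assert n_sig / n_tests <= 0.25


@pytest.fixture()
def funnel_setup():
    """Designed toy: 6 tumors, 8 genes, planted co-occurrence in one cluster."""
    genes = [Gene(f"g{i}", "1", i * 2_000_000, i * 2_000_000 + 10_000) for i in range(8)]
    ann = GenomeAnnotation(
        [("1", 50_000_000)],
        [Arm("1", "1p", 0, 24_000_000), Arm("1", "1q", 26_000_000, 50_000_000)],
        [], genes,
    )
    samples = [f"t{i}" for i in range(6)]
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=samples)
    rng = np.random.default_rng(0)
    nz_vals = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=samples)
    # g0 upregulated in t0,t1 (cluster 1) with gains in both -> stage 3
    nz_vals.loc["g0", ["t0", "t1"]] = 3.0
    # g1 upregulated in t0,t1; gain only in t0 -> stage 2 but not 3
    nz_vals.loc["g1", ["t0", "t1"]] = 2.0
    # g2 upregulated in t0,t1; no alteration -> stage 1 only
    nz_vals.loc["g2", ["t0", "t1"]] = 2.5
    # g3 upregulated in one tumor only -> below recurrence
    nz_vals.loc["g3", "t0"] = 4.0
    status = pd.DataFrame("neutral", index=nz_vals.index, columns=samples)
    status.loc["g0", ["t0", "t1"]] = "gain"
    status.loc["g1", "t0"] = "gain"
    # g4: gains in 2 cluster-1 tumors but never upregulated -> reference only
    status.loc["g4", ["t1", "t2"]] = "gain"
    nz_table = NZScoreTable(
        nz_vals, pd.Series(6, index=nz_vals.index),
        pd.Series(0.0, index=nz_vals.index), pd.Series(1.0, index=nz_vals.index), []
    )
    svs = {s: [] for s in samples}
    return ann, labels, nz_table, status, svs


class TestFunnel:
    def test_stage_sets_match_designed_truth(self, funnel_setup):
        ann, labels, nz_table, status, svs = funnel_setup
        res = cooccurrence_funnel(labels, nz_table, status, svs, ann)
        by_cluster = {f.cluster: f for f in res}
        f1 = by_cluster[1]
        assert f1.recurrently_upregulated == {"g0", "g1", "g2"}
        assert f1.upregulated_with_cnsv_any_tumor == {"g0", "g1"}
        assert f1.upregulated_with_recurrent_cnsv == {"g0"}
        assert "g4" in f1.expressed_with_recurrent_cnsv
        f2 = by_cluster[2]
        assert f2.recurrently_upregulated == set()

    def test_matches_brute_force_recomputation(self, funnel_setup):
        ann, labels, nz_table, status, svs = funnel_setup
        res = cooccurrence_funnel(labels, nz_table, status, svs, ann)
        # exhaustive oracle over genes x tumors
        for f in res:
            members = [s for s in labels.index if labels[s] == f.cluster]
            for gene in nz_table.nz.index:
                up = {s for s in members if nz_table.nz.loc[gene, s] > 1.5}
                alt = {s for s in members if status.loc[gene, s] == "gain"}
                co = up & alt
                assert (gene in f.recurrently_upregulated) == (len(up) >= 2)
                assert (gene in f.upregulated_with_cnsv_any_tumor) == (len(up) >= 2 and len(co) >= 1)
                assert (gene in f.upregulated_with_recurrent_cnsv) == (len(up) >= 2 and len(co) >= 2)

    def test_stage_nesting(self, funnel_setup):
        ann, labels, nz_table, status, svs = funnel_setup
        for f in cooccurrence_funnel(labels, nz_table, status, svs, ann):
            assert f.upregulated_with_recurrent_cnsv <= f.upregulated_with_cnsv_any_tumor
            assert f.upregulated_with_cnsv_any_tumor <= f.recurrently_upregulated
            assert f.counts == {k: len(v) for k, v in {
                "recurrently_upregulated": f.recurrently_upregulated,
                "upregulated_with_cnsv_any_tumor": f.upregulated_with_cnsv_any_tumor,
                "upregulated_with_recurrent_cnsv": f.upregulated_with_recurrent_cnsv,
                "expressed_with_recurrent_cnsv": f.expressed_with_recurrent_cnsv,
            }.items()}

    def test_no_svs_and_neutral_cn_empties_late_stages(self, funnel_setup):
        ann, labels, nz_table, status, svs = funnel_setup
        neutral = pd.DataFrame("neutral", index=status.index, columns=status.columns)
        for f in cooccurrence_funnel(labels, nz_table, neutral, svs, ann):
            assert f.upregulated_with_cnsv_any_tumor == set()
            assert f.upregulated_with_recurrent_cnsv == set()

    def test_breakpoint_exactly_one_mbp_counts(self, funnel_setup):
        ann, labels, nz_table, status, svs = funnel_setup
        neutral = pd.DataFrame("neutral", index=status.index, columns=status.columns)
        gene = ann.gene("g0")  # span [0, 10000)
        sv = MergedSV("DEL", "1", gene.end + 1_000_000, gene.end + 1_200_000,
                      frozenset({"a", "b"}), ("m",), 0.5)
        svs2 = dict(svs)
        svs2["t0"] = [sv]
        svs2["t1"] = [sv]
        res = cooccurrence_funnel(labels, nz_table, neutral, svs2, ann)
        f1 = {f.cluster: f for f in res}[1]
        assert "g0" in f1.upregulated_with_recurrent_cnsv


@pytest.fixture()
def label_setup():
    gene = Gene("G1", "1", 1_000_000, 1_050_000)
    ann = GenomeAnnotation(
        [("1", 50_000_000)],
        [Arm("1", "1p", 0, 24_000_000), Arm("1", "1q", 26_000_000, 50_000_000)],
        [], [gene],
    )
    status = pd.DataFrame({"t1": ["loss"]}, index=["G1"])
    return ann, status


def nz_table_for(value):
    nz = pd.DataFrame({"t1": [value]}, index=["G1"])
    idx = nz.index
    return NZScoreTable(nz, pd.Series(5, index=idx), pd.Series(0.0, index=idx),
                        pd.Series(1.0, index=idx), [])


class TestLabels:
    def test_benign_snv_without_cosmic_not_labeled(self, label_setup):
        ann, status = label_setup
        v = SmallVariant("t1", "1", 1_000_500, "A", "T", "G1", 0.4, 60, 60, 0,
                         "MODERATE", sift_polyphen_benign=True, in_cosmic=False)
        recs = label_gene_alterations({"t1": [v]}, {"t1": []}, status, None, ann)
        assert recs == []
        v2 = SmallVariant("t1", "1", 1_000_500, "A", "T", "G1", 0.4, 60, 60, 0,
                          "MODERATE", sift_polyphen_benign=True, in_cosmic=True)
        recs = label_gene_alterations({"t1": [v2]}, {"t1": []}, status, None, ann)
        assert recs[0].labels == frozenset({"snv"})

    def test_breakpoint_inside_gene_without_rna_still_direct(self, label_setup):
        ann, status = label_setup
        sv = MergedSV("DEL", "1", 1_010_000, 1_020_000, frozenset({"a", "b"}), ("m",), 0.5)
        recs = label_gene_alterations({"t1": []}, {"t1": [sv]}, status, None, ann)
        assert recs[0].labels == frozenset({"sv_bp"})
        assert recs[0].simple_labels == frozenset({"sv"})

    def test_gain_below_expression_threshold_unlabeled(self, label_setup):
        ann, _ = label_setup
        status = pd.DataFrame({"t1": ["gain"]}, index=["G1"])
        recs = label_gene_alterations({"t1": []}, {"t1": []}, status, nz_table_for(1.0), ann)
        assert recs == []

    def test_worked_combination_loss_with_internal_and_nearby_breakpoints(self, label_setup):
        ann, status = label_setup
        inside = MergedSV("DEL", "1", 1_010_000, 1_020_000, frozenset({"a", "b"}), ("m1",), 0.5)
        nearby = MergedSV("DUP", "1", 1_400_000, 1_600_000, frozenset({"a", "b"}), ("m2",), 0.5)
        recs = label_gene_alterations(
            {"t1": []}, {"t1": [inside, nearby]}, status, nz_table_for(-2.5), ann
        )
        assert recs[0].labels == frozenset({"sv_bp", "sv_indirect", "loss"})
        assert recs[0].simple_labels == frozenset({"sv", "cna"})
        table = alteration_table(recs)
        assert table.loc[0, "alteration"] == "loss sv_bp sv_indirect"
        assert table.loc[0, "alteration_simple"] == "cna sv"

    def test_order_insensitive(self, label_setup):
        ann, status = label_setup
        svs = [
            MergedSV("DEL", "1", 1_010_000, 1_020_000, frozenset({"a", "b"}), ("m1",), 0.5),
            MergedSV("DUP", "1", 1_400_000, 1_600_000, frozenset({"a", "b"}), ("m2",), 0.5),
        ]
        a = label_gene_alterations({"t1": []}, {"t1": svs}, status, nz_table_for(-2.5), ann)
        b = label_gene_alterations({"t1": []}, {"t1": svs[::-1]}, status, nz_table_for(-2.5), ann)
        assert a[0].labels == b[0].labels
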