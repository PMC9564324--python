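import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtint.sv import (
    MergedSV,
    SVCall,
    consensus_pipeline,
    filter_allele_fraction,
    filter_population,
    filter_support,
    merge_callers,
    reciprocal_overlap,
)


def make_call(id, caller, chrom="1", start=0, end=100, svtype="DEL", reads=10, af=0.5, **kw):
    return SVCall(id, caller, svtype, chrom, start, end, reads, af, **kw)


class TestReciprocalOverlap:
    def test_identity(self):
        assert reciprocal_overlap(("1", 100, 200), ("1", 100, 200)) == 1.0

    def test_half_overlap(self):
        assert reciprocal_overlap(("1", 0, 100), ("1", 50, 150)) == 0.5

    def test_disjoint_and_cross_chromosome(self):
        assert reciprocal_overlap(("1", 0, 100), ("1", 100, 200)) == 0.0
        assert reciprocal_overlap(("1", 0, 100), ("2", 0, 100)) == 0.0

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(("1", 5, 5), ("1", 0, 100))

    @given(
        st.integers(0, 1000), st.integers(1, 500),
        st.integers(0, 1000), st.integers(1, 500),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = ("1", s1, s1 + l1), ("1", s2, s2 + l2)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0


class TestSupportFilter:
    def test_threshold_boundary(self):
        kept = filter_support([make_call("a", "c1", reads=7), make_call("b", "c1", reads=6)])
        assert [c.id for c in kept] == ["a"]

    def test_empty_and_passthrough(self):
        assert filter_support([]) == []
        calls = [make_call("a", "c1", reads=9), make_call("b", "c1", reads=100)]
        assert filter_support(calls) == calls


class TestPopulationFilter:
    def test_identical_to_popdb_removed(self):
        call = make_call("a", "c1", start=0, end=1000)
        pop = [make_call("p", "pop", start=0, end=1000)]
        assert filter_population([call], pop) == []

    def test_exactly_ninety_percent_kept(self):
        # RO exactly 0.9 is not strictly greater, so the call survives
        call = make_call("a", "c1", start=0, end=1000)
        pop = [make_call("p", "pop", start=0, end=900)]
        assert reciprocal_overlap(("1", 0, 1000), ("1", 0, 900)) == pytest.approx(0.9)
        assert filter_population([call], pop) == [call]

    def test_type_mismatch_not_removed(self):
        call = make_call("a", "c1", svtype="DUP")
        pop = [make_call("p", "pop", svtype="DEL")]
        assert filter_population([call], pop) == [call]

    def test_matches_brute_force_on_random_calls(self, rng):
        calls, pop = [], []
        for i in range(50):
            s = int(rng.integers(0, 10_000))
            l = int(rng.integers(100, 2_000))
            calls.append(make_call(f"c{i}", "c1", start=s, end=s + l,
                                   svtype=["DEL", "DUP"][i % 2]))
        for i in range(30):
            s = int(rng.integers(0, 10_000))
            l = int(rng.integers(100, 2_000))
            pop.append(make_call(f"p{i}", "pop", start=s, end=s + l,
                                 svtype=["DEL", "DUP"][i % 2]))
        expected = [
            c for c in calls
            if not any(
                p.svtype == c.svtype
                and reciprocal_overlap((c.chrom, c.start, c.end), (p.chrom, p.start, p.end)) > 0.9
                for p in pop
            )
        ]
        assert filter_population(calls, pop) == expected


def brute_force_merge(callsets, ro=0.5, min_callers=2):
    """Independent oracle: explicit all-pairs graph + component enumeration."""
    calls = [c for caller in sorted(callsets) for c in callsets[caller]]
    n = len(calls)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = calls[i], calls[j]
        if a.svtype != b.svtype or a.svtype not in ("DEL", "DUP", "INV"):
            continue
        if a.inverted != b.inverted:
            continue
        if reciprocal_overlap((a.chrom, a.start, a.end), (b.chrom, b.start, b.end)) >= ro:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k])
        comps.append(comp)
    out = set()
    for comp in comps:
        members = [calls[k] for k in comp]
        if len({m.caller for m in members}) < min_callers:
            continue
        out.add(frozenset(m.id for m in members))
    return out


def random_callsets(rng, n_calls=60, n_callers=3):
    sets = {f"c{k}": [] for k in range(n_callers)}
    for i in range(n_calls):
        caller = f"c{int(rng.integers(n_callers))}"
        s = int(rng.integers(0, 20_000))
        l = int(rng.integers(200, 3_000))
        sets[caller].append(
            make_call(f"id{i}", caller, chrom=str(int(rng.integers(1, 3))),
                      start=s, end=s + l, svtype=["DEL", "DUP", "INV"][int(rng.integers(3))],
                      reads=int(rng.integers(1, 30)), af=float(rng.uniform(0, 1)))
        )
    return sets


class TestMergeCallers:
    def test_two_callers_identical_coordinates(self):
        sets = {"c1": [make_call("a", "c1")], "c2": [make_call("b", "c2")]}
        merged = merge_callers(sets)
        assert len(merged) == 1
        assert merged[0].callers == frozenset({"c1", "c2"})
        assert (merged[0].start, merged[0].end) == (0, 100)

    def test_single_caller_call_discarded(self):
        sets = {"c1": [make_call("a", "c1")], "c2": []}
        assert merge_callers(sets) == []

    def test_single_linkage_chain_is_one_component(self):
        # RO(A,B) = RO(B,C) = 0.6, RO(A,C) = 0.2 -> one merged SV of 3 members
        a = make_call("A", "c1", start=0, end=1000)
        b = make_call("B", "c2", start=400, end=1400)
        c = make_call("C", "c3", start=800, end=1800)
        assert reciprocal_overlap(("1", 0, 1000), ("1", 400, 1400)) == 0.6
        assert reciprocal_overlap(("1", 0, 1000), ("1", 800, 1800)) == pytest.approx(0.2)
        merged = merge_callers({"c1": [a], "c2": [b], "c3": [c]})
        assert len(merged) == 1
        assert set(merged[0].member_ids) == {"A", "B", "C"}
        oracle = brute_force_merge({"c1": [a], "c2": [b], "c3": [c]})
        assert oracle == {frozenset({"A", "B", "C"})}

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sets = random_callsets(rng)
            merged = merge_callers(sets)
            got = {frozenset(m.member_ids) for m in merged}
            assert got == brute_force_merge(sets)

    def test_invariant_to_caller_and_call_order(self, rng):
        sets = random_callsets(rng)
        merged = merge_callers(sets)
        shuffled = {k: list(reversed(v)) for k, v in reversed(list(sets.items()))}
        assert merge_callers(shuffled) == merged

    def test_idempotent_on_own_output(self, rng):
        sets = random_callsets(rng)
        merged = merge_callers(sets)
        # feed each consensus SV back as two pseudo-callers
        back = {
            "x": [make_call(f"m{i}", "x", chrom=m.chrom, start=m.start, end=m.end,
                            svtype=m.svtype, af=m.allele_fraction) for i, m in enumerate(merged)],
            "y": [make_call(f"n{i}", "y", chrom=m.chrom, start=m.start, end=m.end,
                            svtype=m.svtype, af=m.allele_fraction) for i, m in enumerate(merged)],
        }
        remerged = merge_callers(back)
        assert {(m.chrom, m.start, m.end, m.svtype) for m in remerged} == {
            (m.chrom, m.start, m.end, m.svtype) for m in merged
        }

    def test_bnd_merging_by_breakpoint_distance(self):
        a = make_call("a", "c1", svtype="BND", start=5000, end=5001,
                      chrom2="2", pos2=9000, orient1="+", orient2="-")
        b = make_call("b", "c2", svtype="BND", start=5050, end=5051,
                      chrom2="2", pos2=9060, orient1="+", orient2="-")
        far = make_call("f", "c2", svtype="BND", start=8000, end=8001,
                        chrom2="2", pos2=9000, orient1="+", orient2="-")
        merged = merge_callers({"c1": [a], "c2": [b, far]})
        assert len(merged) == 1
        assert set(merged[0].member_ids) == {"a", "b"}

    def test_fewer_than_two_callsets_rejected(self):
        with pytest.raises(ValueError):
            merge_callers({"c1": []})


class TestAlleleFractionFilter:
    def _merged(self, af):
        return MergedSV("DEL", "1", 0, 100, frozenset({"a", "b"}), ("x",), af)

    def test_strict_boundary(self):
        assert filter_allele_fraction([self._merged(0.10)]) == []
        kept = filter_allele_fraction([self._merged(0.101)])
        assert len(kept) == 1

    def test_all_zero_af_removed(self):
        assert filter_allele_fraction([self._merged(0.0), self._merged(0.0)]) == []


class TestFullChain:
    def test_recovery_of_planted_svs(self, small_cohort):
        """>= 95% of planted somatic SVs seen by >= 2 callers survive the chain."""
        n_recovered = n_seen2 = 0
        for s in small_cohort.samples:
            sets = small_cohort.sv_callsets[s]
            merged = consensus_pipeline(sets, small_cohort.popdb)
            for true_sv in small_cohort.truth.tumors[s].true_svs:
                near = [
                    m for m in merged
                    if m.svtype == true_sv.svtype and m.chrom == true_sv.chrom
                    and abs(m.start - true_sv.start) < 5_000
                ]
                n_seen2 += 1
                if near:
                    n_recovered += 1
        assert n_recovered / n_seen2 >= 0.95

    def test_population_leaks_are_removed(self, small_cohort):
        pop_coords = {(p.chrom, p.start, p.end) for p in small_cohort.popdb}
        for s in small_cohort.samples:
            merged = consensus_pipeline(small_cohort.sv_callsets[s], small_cohort.popdb)
            for m in merged:
                for pc, ps, pe in pop_coords:
                    if m.chrom == pc and m.svtype != "BND":
                        assert reciprocal_overlap((m.chrom, m.start, m.end), (pc, ps, pe)) <= 0.9

    def test_missing_one_caller_degrades_gracefully(self, small_cohort):
        s = small_cohort.samples[0]
        sets = dict(small_cohort.sv_callsets[s])
        sets.pop("callerC")
        merged = consensus_pipeline(sets, small_cohort.popdb)
        assert all(len(m.callers) >= 2 for m in merged)
        assert len(merged) > 0
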