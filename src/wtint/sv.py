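"""Consensus calling of somatic structural variants from multiple callers.

The filter chain mirrors standard multi-caller practice: drop poorly
supported calls (< 7 reads), remove likely germline events matching a
common population-SV database at > 90% reciprocal overlap, merge the
remaining calls across callers at >= 50% reciprocal overlap requiring
support from at least two tools, and finally keep consensus events with
allele fraction > 0.1.

Intervals are 0-based half-open. Breakends (BND) and insertions carry no
meaningful length, so they are matched by per-breakpoint distance with
matching orientations instead of reciprocal overlap.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace

SVTYPES = ("DEL", "DUP", "INV", "INS", "BND")

#: breakpoint distance window (bp) for BND / INS matching
BND_WINDOW = 100


@dataclass(frozen=True)
class SVCall:
    """A single caller's SV: an interval (DEL/DUP/INV/INS) or a breakend pair.

    For BND events one record holds both mates: (chrom, start) and
    (chrom2, pos2) with orientations in {'+', '-'} per mate.
    """

    id: str
    caller: str
    svtype: str
    chrom: str
    start: int
    end: int
    supporting_reads: int = 0
    allele_fraction: float = 0.0
    inverted: bool = False  # inverted-orientation duplication evidence
    chrom2: str | None = None
    pos2: int | None = None
    orient1: str | None = None
    orient2: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype != "BND" and not self.start < self.end:
            raise ValueError(f"call {self.id}: start must be < end for {self.svtype}")
        if self.supporting_reads < 0:
            raise ValueError(f"call {self.id}: negative supporting_reads")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"call {self.id}: allele_fraction outside [0, 1]")
        if self.svtype == "BND" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError(f"call {self.id}: BND requires a mate (chrom2, pos2)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def breakpoints(self) -> list[tuple[str, int]]:
        if self.svtype == "BND":
            return [(self.chrom, self.start), (self.chrom2, self.pos2)]  # type: ignore[list-item]
        return [(self.chrom, self.start), (self.chrom, self.end)]


@dataclass(frozen=True)
class MergedSV:
    """A cross-caller consensus SV (>= 2 distinct callers by construction)."""

    svtype: str
    chrom: str
    start: int
    end: int
    callers: frozenset[str]
    member_ids: tuple[str, ...]
    allele_fraction: float
    inverted: bool = False
    chrom2: str | None = None
    pos2: int | None = None
    orient1: str | None = None
    orient2: str | None = None

    def breakpoints(self) -> list[tuple[str, int]]:
        if self.svtype == "BND":
            return [(self.chrom, self.start), (self.chrom2, self.pos2)]  # type: ignore[list-item]
        return [(self.chrom, self.start), (self.chrom, self.end)]


# ---- primitive ---------------------------------------------------------


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for half-open intervals.

    Different chromosomes give 0.0; zero-length intervals are an error.
    """
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if ea - sa <= 0 or eb - sb <= 0:
        raise ValueError("zero-length interval in reciprocal_overlap")
    if chrom_a != chrom_b:
        return 0.0
    olap = min(ea, eb) - max(sa, sb)
    if olap <= 0:
        return 0.0
    return min(olap / (ea - sa), olap / (eb - sb))


def _interval_like(call: SVCall | MergedSV) -> bool:
    return call.svtype in ("DEL", "DUP", "INV")


def _breakpoint_match(a, b, window: int = BND_WINDOW) -> bool:
    """Mate-wise distance match with orientation agreement (BND/INS)."""
    if a.svtype == "BND":
        pairs = [
            ((a.chrom, a.start, a.orient1), (a.chrom2, a.pos2, a.orient2)),
        ]
        for (c1, p1, o1), (c2, p2, o2) in pairs:
            direct = (
                c1 == b.chrom and abs(p1 - b.start) <= window
                and c2 == b.chrom2 and abs(p2 - b.pos2) <= window
                and (o1 is None or b.orient1 is None or o1 == b.orient1)
                and (o2 is None or b.orient2 is None or o2 == b.orient2)
            )
            swapped = (
                c1 == b.chrom2 and abs(p1 - b.pos2) <= window
                and c2 == b.chrom and abs(p2 - b.start) <= window
                and (o1 is None or b.orient2 is None or o1 == b.orient2)
                and (o2 is None or b.orient1 is None or o2 == b.orient1)
            )
            if direct or swapped:
                return True
        return False
    # INS: single-locus match
    return a.chrom == b.chrom and abs(a.start - b.start) <= window


def _calls_match(a: SVCall, b: SVCall, ro_threshold: float) -> bool:
    if a.svtype != b.svtype:
        return False
    if _interval_like(a):
        if a.inverted != b.inverted:
            return False
        return reciprocal_overlap((a.chrom, a.start, a.end), (b.chrom, b.start, b.end)) >= ro_threshold
    return _breakpoint_match(a, b)


# ---- filter chain ------------------------------------------------------


def filter_support(calls: list[SVCall], min_reads: int = 7) -> list[SVCall]:
    """Keep calls with at least ``min_reads`` supporting reads (order-preserving)."""
    return [c for c in calls if c.supporting_reads >= min_reads]


def filter_population(
    calls: list[SVCall],
    popdb: list[SVCall],
    ro_threshold: float = 0.9,
    bnd_window: int = BND_WINDOW,
) -> list[SVCall]:
    """Remove calls matching a common population variant.

    Interval types are removed on strict > ``ro_threshold`` reciprocal
    overlap with a same-type database entry; BND/INS are matched by
    breakpoint distance within ``bnd_window``.
    """
    kept = []
    for c in calls:
        hit = False
        for p in popdb:
            if c.svtype != p.svtype:
                continue
            if _interval_like(c):
                if reciprocal_overlap((c.chrom, c.start, c.end), (p.chrom, p.start, p.end)) > ro_threshold:
                    hit = True
                    break
            elif _breakpoint_match(c, p, window=bnd_window):
                hit = True
                break
        if not hit:
            kept.append(c)
    return kept


def merge_callers(
    callsets: dict[str, list[SVCall]],
    ro_threshold: float = 0.5,
    min_callers: int = 2,
    clique: bool = False,
) -> list[MergedSV]:
    """Merge per-caller call sets into consensus SVs.

    Builds a match graph (same svtype; reciprocal overlap >= threshold for
    interval types, mate-wise breakpoint distance for BND/INS) and takes
    connected components (single-linkage). Components supported by fewer
    than ``min_callers`` distinct callers are discarded. With
    ``clique=True`` a component is additionally required to be pairwise
    matched, otherwise it is split greedily into maximal matched subsets.

    Consensus coordinates are per-end medians over members; consensus
    allele fraction is the maximum over members (conservative retention).
    Output is sorted by (chrom, start) and independent of input order.
    """
    if len(callsets) < 2:
        raise ValueError("merge_callers requires call sets from >= 2 callers")
    calls: list[SVCall] = []
    for caller in sorted(callsets):
        for c in callsets[caller]:
            if c.caller != caller:
                c = replace(c, caller=caller)
            calls.append(c)
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.caller, c.id))

    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            if _calls_match(calls[i], calls[j], ro_threshold):
                union(i, j)

    components: dict[int, list[SVCall]] = {}
    for i, c in enumerate(calls):
        components.setdefault(find(i), []).append(c)

    groups: list[list[SVCall]] = []
    for root in sorted(components):
        comp = components[root]
        if clique:
            groups.extend(_split_cliques(comp, ro_threshold))
        else:
            groups.append(comp)

    merged: list[MergedSV] = []
    for comp in groups:
        callers = frozenset(c.caller for c in comp)
        if len(callers) < min_callers:
            continue
        merged.append(_consensus(comp))
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.svtype))
    return merged


def _split_cliques(comp: list[SVCall], ro_threshold: float) -> list[list[SVCall]]:
    """Greedy maximal-clique split of a component (deterministic order)."""
    remaining = list(comp)
    out: list[list[SVCall]] = []
    while remaining:
        seed = remaining.pop(0)
        clique = [seed]
        rest = []
        for c in remaining:
            if all(_calls_match(c, m, ro_threshold) for m in clique):
                clique.append(c)
            else:
                rest.append(c)
        remaining = rest
        out.append(clique)
    return out


def _consensus(members: list[SVCall]) -> MergedSV:
    m0 = members[0]
    af = max(c.allele_fraction for c in members)
    ids = tuple(sorted(c.id for c in members))
    callers = frozenset(c.caller for c in members)
    if m0.svtype == "BND":
        # orient mates consistently against the first member before the median
        p1s, p2s = [], []
        for c in members:
            if c.chrom == m0.chrom and abs(c.start - m0.start) <= abs((c.pos2 or 0) - m0.start):
                p1s.append(c.start)
                p2s.append(c.pos2)
            else:
                p1s.append(c.pos2)
                p2s.append(c.start)
        return MergedSV(
            "BND", m0.chrom, int(statistics.median(p1s)), int(statistics.median(p1s)) + 1,
            callers, ids, af, chrom2=m0.chrom2, pos2=int(statistics.median(p2s)),
            orient1=m0.orient1, orient2=m0.orient2,
        )
    start = int(statistics.median([c.start for c in members]))
    end = int(statistics.median([c.end for c in members]))
    if m0.svtype != "INS":
        lo = min(c.start for c in members)
        hi = max(c.end for c in members)
        start, end = max(start, lo), min(end, hi)
    return MergedSV(
        m0.svtype, m0.chrom, start, max(end, start + 1), callers, ids, af,
        inverted=any(c.inverted for c in members),
    )


def filter_allele_fraction(merged: list[MergedSV], threshold: float = 0.1) -> list[MergedSV]:
    """Keep consensus SVs with allele fraction strictly above ``threshold``."""
    return [m for m in merged if m.allele_fraction > threshold]


def consensus_pipeline(
    callsets: dict[str, list[SVCall]],
    popdb: list[SVCall],
    min_reads: int = 7,
    ro_pop: float = 0.9,
    ro_merge: float = 0.5,
    min_callers: int = 2,
    min_af: float = 0.1,
    clique: bool = False,
) -> list[MergedSV]:
    """Full chain: support filter -> population filter -> merge -> AF filter."""
    filtered = {
        caller: filter_population(filter_support(calls, min_reads), popdb, ro_pop)
        for caller, calls in callsets.items()
    }
    merged = merge_callers(filtered, ro_threshold=ro_merge, min_callers=min_callers, clique=clique)
    return filter_allele_fraction(merged, min_af)
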