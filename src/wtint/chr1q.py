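"""Shared 1q-gain region, clonality inference, and mechanism classification.

Gain of 1q can arise through distinct mutational routes that leave
distinct joint CN + SV footprints:

* isochromosome 1q — whole-arm 1p loss and 1q gain of the same abundance
  (one event), with no SV explaining the CN boundaries (the boundary is
  the centromere itself);
* breakage-fusion-bridge — a partial gain bounded by a fold-back
  inversion (two near-coincident inverted breakpoints at the gain
  boundary) with loss or neutral copy number distal to it;
* inverted duplication — a partial gain whose two boundaries coincide
  with the breakpoints of a single inverted-orientation duplication;
* whole-arm gain with or without subsequent unrelated SVs (breakpoints
  not matching any CN segment boundary).

Classification is a deterministic first-match rule cascade with a full
evidence trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .annotation import GenomeAnnotation
from .cn import CNSegment, CR_THRESHOLD, IntervalSummary, summarize_interval
from .sv import MergedSV

MECHANISMS = (
    "isochromosome_like",
    "bfb_like",
    "inverted_duplication",
    "arm_gain_no_sv",
    "arm_gain_with_subsequent_sv",
    "unclassified",
)


# ---- shared gained region ----------------------------------------------


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def gained_intervals(segments: list[CNSegment], arm: tuple[str, int, int],
                     threshold: float = CR_THRESHOLD) -> list[tuple[int, int]]:
    """Merged intervals of gained segments clipped to an arm."""
    chrom, astart, aend = arm
    raw = [
        (max(seg.start, astart), min(seg.end, aend))
        for seg in segments
        if seg.chrom == chrom and seg.log2_copy_ratio > threshold
        and min(seg.end, aend) > max(seg.start, astart)
    ]
    return _merge_intervals(raw)


def shared_gained_region(
    gained_by_tumor: dict[str, list[tuple[int, int]]]
) -> list[tuple[int, int]]:
    """Intersection across tumors of each tumor's union of gained intervals.

    Commutative and associative in tumor order; empty when no base is
    gained in every tumor.
    """
    if not gained_by_tumor:
        raise ValueError("no tumors with a gain on the arm")
    result: list[tuple[int, int]] | None = None
    for sample in sorted(gained_by_tumor):
        merged = _merge_intervals(gained_by_tumor[sample])
        result = merged if result is None else _intersect(result, merged)
    return result or []


# ---- clonality ----------------------------------------------------------


@dataclass(frozen=True)
class ClonalityEstimate:
    expected_cr: float
    expected_maf: float
    observed_cr: float
    observed_maf: float | None
    verdict: str  # clonal | subclonal | indeterminate
    tolerance: float
    extra_copies: int | None = None


def infer_clonality(
    weighted_cr: float,
    weighted_maf: float | None,
    purity: float,
    tol: float = 0.1,
    covered_fraction: float = 1.0,
    max_extra_copies: int = 4,
) -> ClonalityEstimate:
    """Compare an observed arm gain to the clonal expectation at known purity.

    A clonal gain of c extra copies in a tumor of purity p has
    CR = log2((2 + c*p) / 2); for a single extra copy the minor allele
    fraction is ((1-p) + p) / ((1-p)*2 + p*3) = 1 / (2 + p). The verdict is
    ``clonal`` when the observation matches some c in 1..``max_extra_copies``
    within ``tol`` (MAF checked only for c = 1, where the minor copy number
    is determined), ``subclonal`` when the CR falls below the one-copy
    clonal expectation by more than ``tol``, and ``indeterminate`` when the
    arm is poorly covered (< 0.5) or the CR exceeds all tested expectations.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    exp_cr = math.log2((2 + purity) / 2)
    exp_maf = 1.0 / (2.0 + purity)
    if covered_fraction < 0.5:
        return ClonalityEstimate(exp_cr, exp_maf, weighted_cr, weighted_maf, "indeterminate", tol)
    for c in range(1, max_extra_copies + 1):
        ec = math.log2((2 + c * purity) / 2)
        if abs(weighted_cr - ec) <= tol:
            if c == 1 and weighted_maf is not None and abs(weighted_maf - exp_maf) > tol:
                continue
            return ClonalityEstimate(ec, exp_maf, weighted_cr, weighted_maf, "clonal", tol, c)
    if weighted_cr < exp_cr - tol:
        return ClonalityEstimate(exp_cr, exp_maf, weighted_cr, weighted_maf, "subclonal", tol)
    return ClonalityEstimate(exp_cr, exp_maf, weighted_cr, weighted_maf, "indeterminate", tol)


# ---- mechanism classification ------------------------------------------


@dataclass
class MechanismCall:
    sample: str
    mechanism: str
    evidence: list[str] = field(default_factory=list)
    independent_focal_p_loss: bool = False


def _implied_fraction_loss(cr: float) -> float:
    return 2.0 - 2.0 ** (1.0 + cr)


def _implied_fraction_gain(cr: float) -> float:
    return 2.0 ** (1.0 + cr) - 2.0


def _near(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def classify_1q_mechanism(
    sample: str,
    segments: list[CNSegment],
    annotation: GenomeAnnotation,
    merged_svs: list[MergedSV],
    chrom: str = "1",
    boundary_tol: int = 10_000,
    full_arm_fraction: float = 0.9,
    abundance_tol: float = 0.2,
    threshold: float = CR_THRESHOLD,
) -> MechanismCall:
    """Classify the mutational mechanism behind a tumor's 1q gain.

    First-match rule cascade over joint CN and SV evidence; see the module
    docstring for the mechanism definitions. Raises when the sample has no
    gain call on the q arm. Additionally flags an independent focal p-arm
    loss whose boundaries match deletion or breakend SV breakpoints.
    """
    p_arm = annotation.arm(f"{chrom}p")
    q_arm = annotation.arm(f"{chrom}q")
    p_iv = (p_arm.chrom, p_arm.start, p_arm.end)
    q_iv = (q_arm.chrom, q_arm.start, q_arm.end)
    chrom_segs = [s for s in segments if s.chrom == chrom]
    q_gains = gained_intervals(chrom_segs, q_iv, threshold)
    gained_bases = sum(e - s for s, e in q_gains)
    if gained_bases == 0:
        raise ValueError(f"{sample}: no gain on {chrom}q; mechanism undefined")
    q_len = q_arm.end - q_arm.start
    full_q_gain = gained_bases >= full_arm_fraction * q_len

    p_losses = _merge_intervals(
        [
            (max(s.start, p_arm.start), min(s.end, p_arm.end))
            for s in chrom_segs
            if s.log2_copy_ratio < -threshold
            and min(s.end, p_arm.end) > max(s.start, p_arm.start)
        ]
    )
    lost_bases_p = sum(e - s for s, e in p_losses)
    full_p_loss = lost_bases_p >= full_arm_fraction * (p_arm.end - p_arm.start)

    p_summary = summarize_interval(chrom_segs, p_iv, f"{chrom}p", threshold)
    q_summary = summarize_interval(chrom_segs, q_iv, f"{chrom}q", threshold)

    # CN boundaries: internal edges of gained/lost intervals on the chromosome
    cn_boundaries: list[int] = []
    for s, e in q_gains + p_losses:
        cn_boundaries.extend([s, e])

    svs_on_q = [
        sv
        for sv in merged_svs
        if any(c == chrom and q_arm.start <= p < q_arm.end for c, p in sv.breakpoints())
    ]

    def sv_explains_boundaries(sv: MergedSV) -> bool:
        return all(
            any(_near(p, b, boundary_tol) for b in cn_boundaries)
            for c, p in sv.breakpoints()
            if c == chrom
        ) and any(c == chrom for c, _ in sv.breakpoints())

    evidence: list[str] = []
    call = MechanismCall(sample, "unclassified")

    # flag: focal 1p loss mediated by its own SV (deletion / translocation)
    for s, e in p_losses:
        for sv in merged_svs:
            if sv.svtype not in ("DEL", "BND"):
                continue
            bps = [p for c, p in sv.breakpoints() if c == chrom]
            if any(_near(p, s, boundary_tol) or _near(p, e, boundary_tol) for p in bps):
                call.independent_focal_p_loss = True

    # R1: isochromosome-like
    if full_p_loss and full_q_gain and p_summary.weighted_cr is not None and q_summary.weighted_cr is not None:
        f_loss = _implied_fraction_loss(p_summary.weighted_cr)
        f_gain = _implied_fraction_gain(q_summary.weighted_cr)
        same_abundance = abs(f_loss - f_gain) <= abundance_tol
        boundary_sv = any(sv_explains_boundaries(sv) for sv in svs_on_q)
        if same_abundance and not boundary_sv:
            call.mechanism = "isochromosome_like"
            call.evidence = [
                f"full 1p loss (cr={p_summary.weighted_cr:.3f}, implied fraction {f_loss:.2f})",
                f"full 1q gain (cr={q_summary.weighted_cr:.3f}, implied fraction {f_gain:.2f})",
                "no SV explaining the CN boundaries",
            ]
            return call

    # R2: BFB-like fold-back inversion at a partial-gain boundary
    if not full_q_gain:
        for sv in svs_on_q:
            if sv.svtype != "INV":
                continue
            b1, b2 = (p for _, p in sv.breakpoints())
            if abs(b1 - b2) > boundary_tol:
                continue
            for s, e in q_gains:
                boundary = e  # distal edge of the gained interval
                if not (_near(b1, boundary, boundary_tol) and _near(b2, boundary, boundary_tol)):
                    continue
                distal = summarize_interval(chrom_segs, (chrom, boundary, q_arm.end), "distal", threshold)
                if distal.call in ("loss", "neutral", "no_data"):
                    call.mechanism = "bfb_like"
                    call.evidence = [
                        f"partial 1q gain [{s}, {e})",
                        f"fold-back inversion breakpoints {b1}/{b2} at gain boundary {boundary}",
                        f"distal segment call: {distal.call}",
                    ]
                    return call

    # R3: inverted duplication matching both gain boundaries
    if not full_q_gain:
        for sv in svs_on_q:
            if not (sv.svtype in ("DUP", "INV") and sv.inverted):
                continue
            for s, e in q_gains:
                if _near(sv.start, s, boundary_tol) and _near(sv.end, e, boundary_tol):
                    call.mechanism = "inverted_duplication"
                    call.evidence = [
                        f"partial 1q gain [{s}, {e})",
                        f"inverted duplication {sv.start}-{sv.end} matches both gain boundaries",
                    ]
                    return call

    # R4 / R5: whole-arm gain with or without unrelated SVs
    if full_q_gain:
        unrelated = [sv for sv in svs_on_q if not sv_explains_boundaries(sv)]
        if unrelated:
            call.mechanism = "arm_gain_with_subsequent_sv"
            call.evidence = [f"full 1q gain"] + [
                f"SV {sv.svtype} at {sv.breakpoints()} away from CN boundaries" for sv in unrelated
            ]
            return call
        if not svs_on_q:
            call.mechanism = "arm_gain_no_sv"
            call.evidence = ["full 1q gain", "no merged SVs on 1q"]
            return call

    call.evidence = evidence or ["no rule matched"]
    return call
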