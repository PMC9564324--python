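"""Somatic SNV/indel confidence filtering, mutation burden, signature input.

Three steps consumed downstream:

* high-confidence filter — tumor AF > 0.1, autosomes + X, outside blacklist
  regions, and not a dbSNP variant unless also catalogued in COSMIC;
* nonsynonymous mutation burden — MODERATE/HIGH-impact variants in
  protein-coding genes on autosomes only, per Mbp of coding sequence;
* signature-analysis input — deeply covered (DP > 20 in tumor and normal),
  normal-clean, cohort-non-recurrent SNVs, flagging tumors with too few
  (<= 100) remaining SNVs for exclusion from signature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import GenomeAnnotation

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X"}


@dataclass(frozen=True)
class SmallVariant:
    """One somatic SNV or indel with its annotations (pos is 1-based)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None = None
    tumor_af: float = 0.0
    tumor_depth: int = 0
    normal_depth: int = 0
    normal_alt_reads: int = 0
    impact: str = "MODIFIER"
    sift_polyphen_benign: bool = False
    in_dbsnp: bool = False
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_af <= 1.0:
            raise ValueError(f"{self.key()}: tumor_af outside [0, 1]")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError(f"{self.key()}: negative depth")
        if self.impact not in IMPACTS:
            raise ValueError(f"{self.key()}: unknown impact {self.impact!r}")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class BurdenResult:
    n_nonsynonymous: int
    denominator_mbp: float
    burden_per_mbp: float


def filter_high_confidence(
    variants: list[SmallVariant],
    blacklist_regions: list[tuple[str, int, int]] | None = None,
    allowed_chroms: set[str] | None = None,
) -> list[SmallVariant]:
    """Keep high-confidence somatic variants.

    Conditions: tumor AF strictly > 0.1; chromosome in 1-22 or X; not in a
    blacklist interval (0-based half-open); not in dbSNP unless also in
    COSMIC. Chromosome names outside the recognized set raise.
    """
    blacklist = blacklist_regions or []
    allowed = allowed_chroms if allowed_chroms is not None else _VALID_CHROMS
    kept = []
    for v in variants:
        chrom = v.chrom.removeprefix("chr")
        if chrom not in _VALID_CHROMS and chrom not in ("Y", "MT"):
            raise ValueError(f"malformed chromosome name in variant {v.key()}")
        if chrom not in allowed:
            continue
        if v.tumor_af <= 0.1:
            continue
        pos0 = v.pos - 1
        if any(c == v.chrom and s <= pos0 < e for c, s, e in blacklist):
            continue
        if v.in_dbsnp and not v.in_cosmic:
            continue
        kept.append(v)
    return kept


def mutation_burden(
    variants: list[SmallVariant],
    annotation: GenomeAnnotation,
    autosomes: set[str] | None = None,
) -> BurdenResult:
    """Nonsynonymous variants per Mbp of protein-coding sequence.

    The numerator counts MODERATE/HIGH-impact variants lying in
    protein-coding genes on autosomes (X is excluded here even though the
    confidence filter retains it). The denominator is the summed coding
    length of protein-coding genes on the same chromosomes, in Mbp.
    """
    if autosomes is None:
        autosomes = set(annotation.autosome_names())
    coding = annotation.total_coding_bases(chroms=autosomes)
    if coding <= 0:
        raise ValueError("zero coding-sequence denominator")
    pc_genes = {g.gene_id for g in annotation.genes if g.is_protein_coding}
    n = sum(
        1
        for v in variants
        if v.impact in ("MODERATE", "HIGH")
        and v.chrom in autosomes
        and v.gene_id is not None
        and v.gene_id in pc_genes
    )
    denom = coding / 1e6
    return BurdenResult(n, denom, n / denom)


def signature_input_filter(
    variants_by_sample: dict[str, list[SmallVariant]],
    min_depth: int = 20,
    min_snvs_for_signatures: int = 100,
) -> tuple[dict[str, list[SmallVariant]], set[str]]:
    """Build the per-tumor SNV sets feeding mutational-signature extraction.

    Keeps SNVs (indels dropped) with tumor and normal depth strictly >
    ``min_depth``, zero alt-supporting reads in the normal, and no exact
    chrom/pos/ref/alt recurrence in a second patient. Returns the filtered
    sets and the samples excluded from signature analysis because they
    retain <= ``min_snvs_for_signatures`` SNVs.
    """
    counts: dict[tuple[str, int, str, str], set[str]] = {}
    for sample, variants in variants_by_sample.items():
        for v in variants:
            if v.is_snv:
                counts.setdefault(v.key(), set()).add(sample)
    recurrent = {k for k, samples in counts.items() if len(samples) >= 2}

    out: dict[str, list[SmallVariant]] = {}
    excluded: set[str] = set()
    for sample, variants in variants_by_sample.items():
        kept = [
            v
            for v in variants
            if v.is_snv
            and v.tumor_depth > min_depth
            and v.normal_depth > min_depth
            and v.normal_alt_reads == 0
            and v.key() not in recurrent
        ]
        out[sample] = kept
        if len(kept) <= min_snvs_for_signatures:
            excluded.add(sample)
    return out, excluded
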