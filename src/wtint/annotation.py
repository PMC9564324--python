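"""Genome annotation: chromosomes, arms, excluded regions, genes, gene sets.

All coordinates are 0-based, half-open. The annotation serves two purposes:
it is the interval universe against which CN segments are summarized
(arms, cytoband-like excluded regions, gene bodies), and it carries the
coding-length denominator used for mutation-burden normalization.

A miniature genome generator is provided for simulation and testing; real
annotation can be loaded from BED + gene-table TSV + GMT files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    is_protein_coding: bool = True
    coding_bases: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span {self.gene_id}: [{self.start}, {self.end})")
        if self.coding_bases > self.end - self.start:
            raise ValueError(f"gene {self.gene_id}: coding_bases exceeds gene length")


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str  # e.g. "1p", "1q"
    start: int
    end: int


@dataclass
class GenomeAnnotation:
    """Chromosome/arm/gene universe with named gene sets."""

    chromosomes: list[tuple[str, int]]
    arms: list[Arm]
    excluded_regions: list[tuple[str, int, int]]  # acen/gvar/stalk analogs
    genes: list[Gene]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for arm in self.arms:
            if arm.chrom not in lengths or not (0 <= arm.start < arm.end <= lengths[arm.chrom]):
                raise ValueError(f"arm {arm.name} outside chromosome bounds")
        by_chrom: dict[str, list[Arm]] = {}
        for arm in self.arms:
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for a, b in zip(arms, arms[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping arms on chromosome {chrom}")
        for g in self.genes:
            if g.chrom not in lengths or g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")

    # ---- lookups -------------------------------------------------------

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    def arms_of(self, chrom: str) -> list[Arm]:
        return [a for a in self.arms if a.chrom == chrom]

    def gene(self, gene_id: str) -> Gene:
        if not hasattr(self, "_gene_index"):
            self._gene_index = {g.gene_id: g for g in self.genes}
        return self._gene_index[gene_id]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def total_coding_bases(self, chroms: set[str] | None = None) -> int:
        """Sum of coding bases over protein-coding genes, optionally restricted."""
        return sum(
            g.coding_bases
            for g in self.genes
            if g.is_protein_coding and (chroms is None or g.chrom in chroms)
        )

    def autosome_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes if c not in ("X", "Y", "MT")]


DEFAULT_CHROM_SPEC = [("1", 50_000_000), ("2", 50_000_000), ("3", 50_000_000), ("11", 50_000_000)]

_MIN_CHROM_FOR_ARMS = 2_000_000


def generate_annotation(
    seed: int,
    n_genes: int = 500,
    chrom_spec: list[tuple[str, int]] | None = None,
    coding_fraction: float = 0.03,
) -> GenomeAnnotation:
    """Build a deterministic miniature genome.

    Each chromosome is split into a p arm (first 48% of its length), a
    centromeric excluded gap (4%), and a q arm (remaining 48%). Genes of
    10-100 kb are placed uniformly outside excluded regions, with both arms
    guaranteed to receive genes. ``coding_fraction`` of each gene's span is
    recorded as coding sequence.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    chrom_spec = list(chrom_spec) if chrom_spec is not None else list(DEFAULT_CHROM_SPEC)
    for name, length in chrom_spec:
        if length < _MIN_CHROM_FOR_ARMS:
            raise ValueError(f"chromosome {name} too short to host two arms and a centromere")

    rng = np.random.default_rng(seed)
    arms: list[Arm] = []
    excluded: list[tuple[str, int, int]] = []
    for name, length in chrom_spec:
        p_end = int(length * 0.48)
        q_start = int(length * 0.52)
        arms.append(Arm(name, f"{name}p", 0, p_end))
        arms.append(Arm(name, f"{name}q", q_start, length))
        excluded.append((name, p_end, q_start))

    # distribute genes across arms proportionally to arm length, at least 1 per arm
    arm_lengths = np.array([a.end - a.start for a in arms], dtype=float)
    alloc = np.maximum(1, np.floor(n_genes * arm_lengths / arm_lengths.sum()).astype(int))
    while alloc.sum() > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while alloc.sum() < n_genes:
        alloc[int(np.argmin(alloc))] += 1

    genes: list[Gene] = []
    idx = 0
    for arm, k in zip(arms, alloc):
        for _ in range(int(k)):
            size = int(rng.integers(10_000, 100_000))
            start = int(rng.integers(arm.start, max(arm.start + 1, arm.end - size)))
            end = min(start + size, arm.end)
            coding = max(1, int((end - start) * coding_fraction))
            genes.append(Gene(f"G{idx:04d}", arm.chrom, start, end, True, coding))
            idx += 1
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    # named gene sets: a Wnt-pathway analog and a cancer-gene analog
    ids = [g.gene_id for g in genes]
    wnt = sorted(rng.choice(ids, size=min(25, len(ids)), replace=False).tolist())
    remaining = sorted(set(ids) - set(wnt))
    cancer = sorted(
        rng.choice(remaining, size=min(40, len(remaining)), replace=False).tolist()
    ) if remaining else []
    gene_sets = {"WNT_SIGNALING": wnt, "CANCER_GENES": cancer}

    return GenomeAnnotation(chrom_spec, arms, excluded, genes, gene_sets)


# ---- file I/O ----------------------------------------------------------


def write_annotation(ann: GenomeAnnotation, outdir: str | Path) -> None:
    """Write arms/excluded regions as BED, genes as TSV, gene sets as GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "chromosomes.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "length"])
        for name, length in ann.chromosomes:
            w.writerow([name, length])
    with open(outdir / "arms.bed", "w", newline="") as fh:
        for a in ann.arms:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")
    with open(outdir / "excluded.bed", "w", newline="") as fh:
        for chrom, s, e in ann.excluded_regions:
            fh.write(f"{chrom}\t{s}\t{e}\texcluded\n")
    with open(outdir / "genes.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "chrom", "start", "end", "is_protein_coding", "coding_bases"])
        for g in ann.genes:
            w.writerow([g.gene_id, g.chrom, g.start, g.end, int(g.is_protein_coding), g.coding_bases])
    with open(outdir / "gene_sets.gmt", "w") as fh:
        for name, members in ann.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_annotation(indir: str | Path) -> GenomeAnnotation:
    indir = Path(indir)
    chromosomes = []
    with open(indir / "chromosomes.tsv") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            chromosomes.append((row["chrom"], int(row["length"])))
    arms = []
    with open(indir / "arms.bed") as fh:
        for line in fh:
            chrom, s, e, name = line.rstrip("\n").split("\t")
            arms.append(Arm(chrom, name, int(s), int(e)))
    excluded = []
    with open(indir / "excluded.bed") as fh:
        for line in fh:
            chrom, s, e, _ = line.rstrip("\n").split("\t")
            excluded.append((chrom, int(s), int(e)))
    genes = []
    with open(indir / "genes.tsv") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            genes.append(
                Gene(
                    row["gene_id"], row["chrom"], int(row["start"]), int(row["end"]),
                    bool(int(row["is_protein_coding"])), int(row["coding_bases"]),
                )
            )
    gene_sets = read_gmt(indir / "gene_sets.gmt")
    return GenomeAnnotation(chromosomes, arms, excluded, genes, gene_sets)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                sets[parts[0]] = [p for p in parts[2:] if p]
    return sets
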