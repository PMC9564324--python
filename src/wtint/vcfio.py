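"""VCF 4.2 reading/writing for SV call sets.

Interval SVs (DEL/DUP/INV/INS) are written with symbolic ALT alleles and
an END INFO field; breakend events are written as paired BND records with
MATEID and bracket notation encoding mate orientation. Positions convert
between the package's 0-based half-open convention and VCF's 1-based
inclusive one. Reading uses cyvcf2 and re-joins BND mate pairs into
single records.
"""

from __future__ import annotations

from pathlib import Path

from cyvcf2 import VCF

from .annotation import GenomeAnnotation
from .sv import SVCall

_HEADER_INFO = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##INFO=<ID=INVDUP,Number=0,Type=Flag,Description="Inverted-orientation duplication evidence">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller">
"""


def _bnd_alt(chrom2: str, pos2_1based: int, orient: str | None) -> str:
    if orient == "-":
        return f"N]{chrom2}:{pos2_1based}]"
    return f"N[{chrom2}:{pos2_1based}["


def write_sv_vcf(calls: list[SVCall], path: str | Path, annotation: GenomeAnnotation | None = None) -> None:
    lines = [_HEADER_INFO.rstrip("\n")]
    if annotation is not None:
        for chrom, length in annotation.chromosomes:
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = []
    for c in calls:
        common = f"SR={c.supporting_reads};AF={c.allele_fraction:.4f};CALLER={c.caller}"
        if c.svtype == "BND":
            pos1 = c.start + 1
            pos2 = (c.pos2 or 0) + 1
            id1, id2 = f"{c.id}_1", f"{c.id}_2"
            alt1 = _bnd_alt(c.chrom2 or "", pos2, c.orient2)
            alt2 = _bnd_alt(c.chrom, pos1, c.orient1)
            rows.append((c.chrom, pos1, f"{id1}\tN\t{alt1}\t.\tPASS\tSVTYPE=BND;MATEID={id2};{common}"))
            rows.append((c.chrom2, pos2, f"{id2}\tN\t{alt2}\t.\tPASS\tSVTYPE=BND;MATEID={id1};{common}"))
        else:
            info = f"SVTYPE={c.svtype};END={c.end};{common}"
            if c.inverted:
                info += ";INVDUP"
            rows.append((c.chrom, c.start + 1, f"{c.id}\tN\t<{c.svtype}>\t.\tPASS\t{info}"))
    rows.sort(key=lambda r: (str(r[0]), r[1]))
    for chrom, pos, rest in rows:
        lines.append(f"{chrom}\t{pos}\t{rest}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sv_vcf(path: str | Path, default_caller: str = "unknown") -> list[SVCall]:
    """Read SVs from VCF, joining BND mate pairs into single records."""
    calls: list[SVCall] = []
    bnd_records: dict[str, dict] = {}
    for var in VCF(str(path)):
        info = dict(var.INFO)
        svtype = info.get("SVTYPE", "DEL")
        caller = info.get("CALLER", default_caller)
        reads = int(info.get("SR", 0))
        af = float(info.get("AF", 0.0))
        if svtype == "BND":
            bnd_records[var.ID] = {
                "chrom": var.CHROM,
                "pos0": var.POS - 1,
                "alt": var.ALT[0],
                "mateid": info.get("MATEID"),
                "reads": reads,
                "af": af,
                "caller": caller,
            }
            continue
        end = int(info.get("END", var.POS))
        calls.append(
            SVCall(var.ID, caller, svtype, var.CHROM, var.POS - 1, end, reads, af,
                   inverted="INVDUP" in info)
        )
    seen = set()
    for vid, rec in bnd_records.items():
        if vid in seen:
            continue
        mate_id = rec["mateid"]
        mate = bnd_records.get(mate_id)
        if mate is None:
            raise ValueError(f"unpaired BND record {vid}")
        seen.update({vid, mate_id})
        orient2 = "-" if "]" in rec["alt"] else "+"
        orient1 = "-" if "]" in mate["alt"] else "+"
        base = vid[:-2] if vid.endswith(("_1", "_2")) else vid
        calls.append(
            SVCall(base, rec["caller"], "BND", rec["chrom"], rec["pos0"], rec["pos0"] + 1,
                   rec["reads"], rec["af"], False, mate["chrom"], mate["pos0"],
                   orient1, orient2)
        )
    return calls
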