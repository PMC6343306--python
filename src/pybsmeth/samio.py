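"""Minimal SAM text emission plus pysam-backed reading.

Writing is done by hand so output is deterministic byte-for-byte;
reading goes through :mod:`pysam` so downstream code gets fully parsed
records (CIGAR, aligned pairs, tags).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0  # 0-based; written as 1-based
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: list[tuple[str, str, object]] = field(default_factory=list)

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos + 1 if self.rname != "*" else 0),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext + 1 if self.rnext != "*" else 0),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        for tag, typ, val in self.tags:
            fields.append(f"{tag}:{typ}:{val}")
        return "\t".join(fields)


def header_lines(
    chrom_names: Iterable[str],
    chrom_lengths: dict[str, int],
    program_args: Optional[str] = None,
) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in chrom_names:
        lines.append(f"@SQ\tSN:{name}\tLN:{chrom_lengths[name]}")
    pg = "@PG\tID:pybsmeth\tPN:pybsmeth\tVN:0.1.0"
    if program_args:
        pg += f"\tCL:{program_args}"
    lines.append(pg)
    return lines


def write_sam(path, header: list[str], records: Iterable[SamRecord]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_sam(path) -> Iterator[pysam.AlignedSegment]:
    """Iterate pysam records from a SAM text file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


def cigar_read_length(cigar: str) -> int:
    """Sum of read-consuming (M/I/S/=/X) operation lengths."""
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


def cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops
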