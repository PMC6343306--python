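"""Per-cytosine methylation calling from aligned bisulfite reads.

Counting is strand-aware in plus-strand SAM layout.  A plus-strand
cytosine (reference C) gets its C/T counts from reads whose bisulfite
space is C2T; the opposite-strand (G2A) reads covering the same column
show C (no SNP) or T (putative C->T SNP) in plus layout and feed the
rev_G/rev_A correction counts.  Minus-strand cytosines (reference G) are
the mirror image: G2A reads provide G (methylated) / A (unmethylated)
counts and C2T reads provide the reverse-strand correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .genome_index import ReferenceGenome
from . import samio

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

MISSING = float("nan")


@dataclass
class CytosineRecord:
    chrom: str
    pos: int  # 0-based
    strand: str  # + / -
    context: str  # CpG / CHG / CHH
    count_C: int
    count_T: int
    rev_G: int
    rev_A: int
    ml: Optional[float]  # percentage in [0, 100], None when flagged missing
    snp_flag: bool

    @property
    def depth(self) -> int:
        return self.count_C + self.count_T


def methylation_level(
    count_C: int,
    count_T: int,
    rev_G: int,
    rev_A: int,
    rev_threshold: int = 10,
) -> tuple[Optional[float], bool]:
    """Reverse-strand corrected methylation level as a percentage.

    With sufficient reverse coverage (rev_G + rev_A >= rev_threshold)
    the C/T ratio is corrected by the fraction of reverse reads showing
    G and capped at 1.0; below the threshold the plain C/(C+T) ratio is
    used.  A site with adequate reverse coverage but rev_G == 0 looks
    like a homozygous C->T SNP: it is flagged and no level is reported.

    Returns (ml or None, snp_flag).
    """
    depth = count_C + count_T
    if depth <= 0:
        raise ValueError("methylation level undefined at zero C+T depth")
    rev_cov = rev_G + rev_A
    if rev_cov >= rev_threshold:
        if rev_G == 0:
            return None, True
        ml = min(count_C / (depth * (rev_G / rev_cov)), 1.0) * 100.0
        return ml, False
    return count_C / depth * 100.0, False


def assign_context(
    genome: ReferenceGenome, chrom: str, pos: int, strand: str
) -> str:
    """Sequence context (CpG/CHG/CHH) of the cytosine at (pos, strand)."""
    seq = genome.seqs[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}+ is not a cytosine")
        b1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        b2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    else:
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}- is not a cytosine")
        b1 = _COMP[seq[pos - 1]] if pos - 1 >= 0 else "N"
        b2 = _COMP[seq[pos - 2]] if pos - 2 >= 0 else "N"
    if b1 == "G":
        return "CpG"
    if b1 in "ACT" and b2 == "G":
        return "CHG"
    return "CHH"  # includes N / chromosome-edge fallback


def _infer_space(read) -> str:
    """Bisulfite space of a pysam record (XB tag, else flag heuristic)."""
    try:
        return read.get_tag("XB")
    except KeyError:
        if read.is_paired and read.is_read2:
            return "G2A" if not read.is_reverse else "C2T"
        return "G2A" if read.is_reverse else "C2T"


def pileup(
    sam_path,
    genome: ReferenceGenome,
    min_base_q: int = 20,
    min_mapq: int = 1,
    rev_threshold: int = 10,
    dedup_overlap: bool = True,
) -> list[CytosineRecord]:
    """Pile up a SAM stream over every reference cytosine.

    Reads with mapping quality below ``min_mapq`` (ambiguous placements)
    and bases below ``min_base_q`` are excluded.  Overlapping mates of a
    proper pair are counted once (first mate encountered wins).  Bases
    under D operations contribute nothing; I and S bases consume read
    but no reference, which pysam's aligned pairs already encode.
    """
    counts = {
        space: {n: np.zeros((len(genome.seqs[n]), 4), dtype=np.int32) for n in genome.names}
        for space in ("C2T", "G2A")
    }
    mate_spans: dict[str, tuple[str, int, int]] = {}
    for read in samio.read_sam(sam_path):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        chrom = read.reference_name
        if chrom not in genome.seqs:
            continue
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None or quals is None:
            continue
        if samio.cigar_read_length(read.cigarstring) != len(seq):
            raise ValueError(f"{read.query_name}: CIGAR/sequence length mismatch")
        space = _infer_space(read)
        pairs = read.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        mask = np.frombuffer(seq.encode(), dtype=np.uint8)[qpos]
        keep = np.array(quals, dtype=np.int32)[qpos] >= min_base_q
        if dedup_overlap and read.is_paired and read.is_proper_pair:
            key = read.query_name
            prev = mate_spans.get(key)
            if prev is None:
                mate_spans[key] = (chrom, read.reference_start, read.reference_end)
            elif prev[0] == chrom:
                keep &= ~((rpos >= prev[1]) & (rpos < prev[2]))
        base_idx = np.full(len(mask), -1, dtype=np.int64)
        for base, idx in _BASE_IDX.items():
            base_idx[mask == ord(base)] = idx
        keep &= base_idx >= 0
        np.add.at(counts[space][chrom], (rpos[keep], base_idx[keep]), 1)
    records: list[CytosineRecord] = []
    A, C, G, T = 0, 1, 2, 3
    for chrom in genome.names:
        seq_arr = np.frombuffer(genome.seqs[chrom].encode(), dtype=np.uint8)
        fwd = counts["C2T"][chrom]
        rev = counts["G2A"][chrom]
        for pos in np.flatnonzero(seq_arr == ord("C")):
            pos = int(pos)
            cC, cT = int(fwd[pos, C]), int(fwd[pos, T])
            rG, rA = int(rev[pos, C]), int(rev[pos, T])
            if cC + cT == 0:
                continue
            ml, snp = methylation_level(cC, cT, rG, rA, rev_threshold)
            records.append(
                CytosineRecord(chrom, pos, "+", assign_context(genome, chrom, pos, "+"),
                               cC, cT, rG, rA, ml, snp)
            )
        for pos in np.flatnonzero(seq_arr == ord("G")):
            pos = int(pos)
            cC, cT = int(rev[pos, G]), int(rev[pos, A])
            rG, rA = int(fwd[pos, G]), int(fwd[pos, A])
            if cC + cT == 0:
                continue
            ml, snp = methylation_level(cC, cT, rG, rA, rev_threshold)
            records.append(
                CytosineRecord(chrom, pos, "-", assign_context(genome, chrom, pos, "-"),
                               cC, cT, rG, rA, ml, snp)
            )
    chrom_rank = {n: i for i, n in enumerate(genome.names)}
    records.sort(key=lambda r: (chrom_rank[r.chrom], r.pos, r.strand))
    return records


def filter_depth(
    records: Iterable[CytosineRecord], min_depth: int = 5
) -> list[CytosineRecord]:
    """Keep records whose C+T depth is strictly greater than min_depth."""
    return [r for r in records if r.depth > min_depth]


# ---------------------------------------------------------------------------
# tabular output


TABLE_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "count_C", "count_T", "rev_G", "rev_A", "ml", "snp_flag",
]


def records_to_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.context, r.count_C, r.count_T,
         r.rev_G, r.rev_A, MISSING if r.ml is None else r.ml, r.snp_flag)
        for r in records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_meth_table(records: Iterable[CytosineRecord], path) -> None:
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_meth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_bedgraph(
    records: Iterable[CytosineRecord], path, context: Optional[str] = None,
    min_depth: int = 5,
) -> None:
    """bedGraph of per-site levels (0-based half-open, value = ml / 100)."""
    with open(path, "w") as fh:
        for r in records:
            if context is not None and r.context != context:
                continue
            if r.ml is None or r.depth <= min_depth:
                continue
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.ml / 100.0:.6g}\n")
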