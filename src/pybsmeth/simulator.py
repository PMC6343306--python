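"""Synthetic genomes, methylomes and bisulfite reads with known truth,
plus alignment scoring by position/strand/indel criteria and a paired
concordance evaluation.

A simulated read is built in plus-strand layout (walking the reference,
optionally injecting indels), bisulfite-converted according to its
protocol strand, then substitution errors are applied and the raw
sequence is reverse-complemented for minus-strand reads.  Truth records
keep everything in plus layout so they compare directly against SAM.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_index import ReferenceGenome, revcomp
from . import samio

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    read_id: str
    mate: int  # 0 single-end, else 1/2
    chrom: str
    start: int  # leftmost 0-based reference coordinate
    strand: str  # reported alignment strand
    bs_space: str  # C2T / G2A
    indels: list[tuple[int, int, str]]  # (plus-layout read offset, length, I/D)
    n_errors: int
    meth_states: str  # 0/1 flags of bisulfite-strand cytosines in the read


TRUTH_COLUMNS = [
    "read_id", "mate", "chrom", "start", "strand", "bs_space",
    "indels", "n_errors", "meth_states",
]


def truth_to_frame(truths: Sequence[SimTruth]) -> pd.DataFrame:
    rows = [
        (t.read_id, t.mate, t.chrom, t.start, t.strand, t.bs_space,
         ";".join(f"{o}:{l}:{k}" for o, l, k in t.indels) or ".",
         t.n_errors, t.meth_states or ".")
        for t in truths
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def parse_indels(text: str) -> list[tuple[int, int, str]]:
    if not text or text == ".":
        return []
    out = []
    for item in text.split(";"):
        o, l, k = item.split(":")
        out.append((int(o), int(l), k))
    return out


# ---------------------------------------------------------------------------
# genome / methylome


def simulate_genome(
    length: int, gc_fraction: float = 0.42, seed: int = 0, name: str = "chr1"
) -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ReferenceGenome([name], {name: seq})


@dataclass
class Methylome:
    """Per-cytosine methylation flags on both strands, plus coordinates."""

    plus: dict[str, np.ndarray]  # bool per position; meaningful at ref C
    minus: dict[str, np.ndarray]  # bool per position; meaningful at ref G

    def is_methylated(self, chrom: str, pos: int, strand: str) -> bool:
        arr = self.plus if strand == "+" else self.minus
        return bool(arr[chrom][pos])


def simulate_methylome(
    genome: ReferenceGenome,
    p_cpg: float = 0.8,
    p_chg: float = 0.05,
    p_chh: float = 0.02,
    seed: int = 0,
) -> Methylome:
    """Independently methylate each cytosine at its context's probability."""
    from .meth_caller import assign_context

    probs = {"CpG": p_cpg, "CHG": p_chg, "CHH": p_chh}
    rng = np.random.default_rng(seed)
    plus, minus = {}, {}
    for chrom in genome.names:
        seq = genome.seqs[chrom]
        n = len(seq)
        plus[chrom] = np.zeros(n, dtype=bool)
        minus[chrom] = np.zeros(n, dtype=bool)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for pos in np.flatnonzero(arr == ord("C")):
            ctx = assign_context(genome, chrom, int(pos), "+")
            plus[chrom][pos] = rng.random() < probs[ctx]
        for pos in np.flatnonzero(arr == ord("G")):
            ctx = assign_context(genome, chrom, int(pos), "-")
            minus[chrom][pos] = rng.random() < probs[ctx]
    return Methylome(plus, minus)


# ---------------------------------------------------------------------------
# reads


def _walk_segment(
    seq: str,
    start: int,
    read_len: int,
    rng: np.random.Generator,
    indel_rate: float,
    max_indel_len: int,
    forced_indel: Optional[tuple[int, int, str]] = None,
) -> Optional[tuple[list[str], list[Optional[int]], list[tuple[int, int, str]]]]:
    """Walk the reference collecting read_len plus-layout bases.

    Returns (bases, ref positions per base or None for insertions,
    indels) or None if the chromosome ends first.
    """
    bases: list[str] = []
    refpos: list[Optional[int]] = []
    indels: list[tuple[int, int, str]] = []
    p = start
    while len(bases) < read_len:
        if p >= len(seq):
            return None
        off = len(bases)
        forced_here = forced_indel is not None and forced_indel[0] == off and not indels
        spontaneous = (
            forced_indel is None and off > 0 and rng.random() < indel_rate
        )
        if forced_here or spontaneous:
            if forced_here:
                _, length, kind = forced_indel
            else:
                length = int(rng.integers(1, max_indel_len + 1))
                kind = "D" if rng.random() < 0.5 else "I"
            if kind == "D":
                indels.append((off, length, "D"))
                p += length
                continue
            length = min(length, read_len - off)
            if length > 0:
                indels.append((off, length, "I"))
                for _ in range(length):
                    bases.append(str(rng.choice(_BASES)))
                    refpos.append(None)
                continue
        bases.append(seq[p])
        refpos.append(p)
        p += 1
    return bases, refpos, indels


def _apply_bisulfite(
    bases: list[str],
    refpos: list[Optional[int]],
    chrom: str,
    bs_space: str,
    methylome: Optional[Methylome],
    conversion_rate: float,
    rng: np.random.Generator,
) -> str:
    """Convert the bisulfite strand's cytosines in plus layout.

    C2T space converts plus-strand Cs to T; G2A space converts
    minus-strand Cs, which appear as plus-layout G -> A.
    """
    states = []
    for i, (b, rp) in enumerate(zip(bases, refpos)):
        if rp is None:
            continue
        if bs_space == "C2T" and b == "C":
            meth = methylome.is_methylated(chrom, rp, "+") if methylome else False
            states.append("1" if meth else "0")
            if not meth and rng.random() < conversion_rate:
                bases[i] = "T"
        elif bs_space == "G2A" and b == "G":
            meth = methylome.is_methylated(chrom, rp, "-") if methylome else False
            states.append("1" if meth else "0")
            if not meth and rng.random() < conversion_rate:
                bases[i] = "A"
    return "".join(states)


def _apply_errors(
    bases: list[str], rng: np.random.Generator, error_rate: float, cap: Optional[int]
) -> int:
    n_err = int(rng.binomial(len(bases), error_rate))
    if cap is not None:
        n_err = min(n_err, cap)
    if n_err == 0:
        return 0
    positions = rng.choice(len(bases), size=n_err, replace=False)
    for pos in positions:
        old = bases[pos]
        choices = [b for b in "ACGT" if b != old]
        bases[pos] = choices[int(rng.integers(0, 3))]
    return n_err


def simulate_reads(
    genome: ReferenceGenome,
    methylome: Optional[Methylome],
    n_reads: int,
    read_len: int = 100,
    paired: bool = False,
    insert_mean: int = 500,
    conversion_rate: float = 0.99,
    error_rate: float = 0.01,
    indel_rate: float = 0.0003,
    max_indel_len: int = 10,
    error_cap: Optional[int] = 2,
    base_quality: int = 30,
    seed: int = 0,
    forced_indel: Optional[tuple[int, int, int]] = None,
) -> tuple[list[tuple[str, str, str]], list[SimTruth]]:
    """Simulate single- or paired-end directional bisulfite reads.

    Returns (fastq records, truth records); a fastq record is
    (read id, sequence, quality string).  Paired mode draws the insert
    from Normal(insert_mean, insert_mean/10) truncated to at least
    read_len.  ``forced_indel`` = (min_len, max_len, margin) plants
    exactly one indel per read at a uniform offset inside the margins
    instead of the per-base indel process.
    """
    max_chrom = max(genome.lengths.values())
    if read_len > max_chrom:
        raise ValueError("read_len exceeds genome length")
    if paired and insert_mean < read_len:
        raise ValueError("insert_mean shorter than read_len")
    rng = np.random.default_rng(seed)
    chroms = list(genome.names)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    qual = chr(base_quality + 33) * read_len
    fastq: list[tuple[str, str, str]] = []
    truths: list[SimTruth] = []
    made = 0
    attempts = 0
    while made < n_reads:
        attempts += 1
        if attempts > 50 * n_reads + 100:
            raise RuntimeError("too many rejected simulation attempts")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        seq = genome.seqs[chrom]
        plus_fragment = rng.random() < 0.5  # which strand the protocol converted
        if paired:
            insert = int(round(rng.normal(insert_mean, insert_mean / 10)))
            insert = max(insert, read_len)
            if insert > len(seq):
                continue
            frag_start = int(rng.integers(0, len(seq) - insert + 1))
            left, right = frag_start, frag_start + insert - read_len
            # mate 1 reads the converted strand from its 5' end: the left
            # fragment end for a plus-strand molecule, the right end for minus
            ends = [(left, 1), (right, 2)] if plus_fragment else [(right, 1), (left, 2)]
        else:
            margin = read_len + (max_indel_len + 2 if indel_rate or forced_indel else 0)
            if len(seq) < margin + 1:
                continue
            frag_start = int(rng.integers(0, len(seq) - margin + 1))
            ends = [(frag_start, 0)]
        bs_space = "C2T" if plus_fragment else "G2A"
        reads_here = []
        ok = True
        for start, mate in ends:
            forced = None
            if forced_indel is not None:
                lo, hi, marg = forced_indel
                length = int(rng.integers(lo, hi + 1))
                off = int(rng.integers(marg, read_len - marg))
                kind = "D" if rng.random() < 0.5 else "I"
                forced = (off, length, kind)
            walked = _walk_segment(
                seq, start, read_len, rng,
                0.0 if forced_indel is not None else indel_rate,
                max_indel_len, forced,
            )
            if walked is None:
                ok = False
                break
            bases, refpos, indels = walked
            if "N" in bases:
                ok = False
                break
            states = _apply_bisulfite(
                bases, refpos, chrom, bs_space, methylome, conversion_rate, rng
            )
            n_err = _apply_errors(bases, rng, error_rate, error_cap)
            layout = "".join(bases)
            # mate 1 reads the converted strand, mate 2 its complement;
            # single-end reads the converted strand only.
            if mate == 2:
                strand = "+" if not plus_fragment else "-"
            else:
                strand = "+" if plus_fragment else "-"
            raw = layout if strand == "+" else revcomp(layout)
            reads_here.append((mate, start, strand, raw, indels, n_err, states))
        if not ok:
            continue
        rid = f"sim{made}"
        for mate, start, strand, raw, indels, n_err, states in reads_here:
            suffix = f"/{mate}" if mate else ""
            fastq.append((rid + suffix, raw, qual))
            truths.append(
                SimTruth(rid, mate, chrom, start, strand, bs_space,
                         indels, n_err, states)
            )
        made += 1
    return fastq, truths


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    n_correct: int = 0
    n_wrong: int = 0
    n_unmapped: int = 0
    failures: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_correct + self.n_wrong + self.n_unmapped

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_wrong": self.n_wrong,
            "n_unmapped": self.n_unmapped,
            "accuracy": self.accuracy,
            "failures": dict(sorted(self.failures.items())),
        }


def _cigar_indels(cigar_ops: list[tuple[int, int]]) -> list[tuple[int, int, str]]:
    """(read offset, length, kind) of I/D ops from pysam cigartuples."""
    out = []
    qoff = 0
    for op, length in cigar_ops:
        if op in (0, 7, 8):  # M/=/X
            qoff += length
        elif op == 1:  # I
            out.append((qoff, length, "I"))
            qoff += length
        elif op == 4:  # S
            qoff += length
        elif op == 2:  # D
            out.append((qoff, length, "D"))
    return out


def _indels_similar(
    truth: list[tuple[int, int, str]],
    found: list[tuple[int, int, str]],
    len_tol: int = 1,
    off_tol: int = 5,
) -> bool:
    """Every truth indel matched by a CIGAR indel of the same type within
    tolerance, and vice versa."""
    def matched(a, pool):
        return any(
            k == a[2] and abs(l - a[1]) <= len_tol and abs(o - a[0]) <= off_tol
            for o, l, k in pool
        )

    return all(matched(t, found) for t in truth) and all(
        matched(f, truth) for f in found
    )


def evaluate_alignments(
    truth: pd.DataFrame,
    sam_path,
    pos_tol: int = 10,
    mm_tol: int = 2,
) -> EvalReport:
    """Score a SAM file against simulation truth.

    A read is correct iff (1) it is mapped with mapping quality > 0 on
    the simulated strand, (2) its leftmost position is within
    ``pos_tol`` bases of the true start, and (3) its CIGAR indels match
    the simulated indels (same type, length within 1, read offset
    within 5, both directions) and its mismatch count is within
    ``mm_tol`` of the injected substitution errors.
    """
    idx = {}
    for row in truth.itertuples(index=False):
        idx[(row.read_id, int(row.mate))] = row
    report = EvalReport()
    seen = set()
    for read in samio.read_sam(sam_path):
        if read.is_secondary or read.is_supplementary:
            continue
        name = read.query_name
        mate = 0
        if read.is_paired:
            mate = 1 if read.is_read1 else 2
        elif "/" in name:
            name, m = name.rsplit("/", 1)
            if m in ("1", "2"):
                mate = int(m)
        key = (name, mate)
        if key not in idx:
            raise KeyError(f"read {read.query_name} not present in truth table")
        seen.add(key)
        row = idx[key]
        if read.is_unmapped:
            report.n_unmapped += 1
            continue
        fails = []
        strand = "-" if read.is_reverse else "+"
        if read.mapping_quality <= 0:
            fails.append("mapq")
        if strand != row.strand or read.reference_name != row.chrom:
            fails.append("strand_or_chrom")
        if abs(read.reference_start - int(row.start)) > pos_tol:
            fails.append("position")
        truth_indels = parse_indels(row.indels)
        found = _cigar_indels(read.cigartuples or [])
        if not _indels_similar(truth_indels, found):
            fails.append("indels")
        try:
            nm = read.get_tag("NM")
            if abs(int(nm) - int(row.n_errors)) > mm_tol:
                fails.append("mismatches")
        except KeyError:
            pass
        if fails:
            report.n_wrong += 1
            for f in fails:
                report.failures[f] = report.failures.get(f, 0) + 1
        else:
            report.n_correct += 1
    missing = set(idx) - seen
    report.n_unmapped += len(missing)
    return report


def concordance_eval(sam_paths: Sequence, max_dist: int = 500) -> pd.DataFrame:
    """Concordance of independently aligned mates, cumulative by mapq.

    Mates pair by read name after stripping a /1 or /2 suffix.  A pair
    is concordant iff both mates are mapped to the same chromosome with
    leftmost positions at most ``max_dist`` apart.  Pairs with an
    unmapped mate are excluded and reported separately.
    """
    mates: dict[str, dict[int, tuple]] = {}
    for path in sam_paths:
        for read in samio.read_sam(path):
            if read.is_secondary or read.is_supplementary:
                continue
            name = read.query_name
            mate = 1
            if "/" in name:
                name, m = name.rsplit("/", 1)
                mate = int(m)
            elif read.is_paired:
                mate = 1 if read.is_read1 else 2
            rec = None
            if not read.is_unmapped:
                rec = (read.reference_name, read.reference_start, read.mapping_quality)
            mates.setdefault(name, {})[mate] = rec
    pairs = []
    n_excluded = 0
    for name, d in mates.items():
        a, b = d.get(1), d.get(2)
        if a is None or b is None:
            n_excluded += 1
            continue
        conc = a[0] == b[0] and abs(a[1] - b[1]) <= max_dist
        pairs.append((min(a[2], b[2]), conc))
    rows = []
    thresholds = sorted({q for q, _ in pairs}, reverse=True) or [0]
    for thr in thresholds:
        nc = sum(1 for q, c in pairs if q >= thr and c)
        nd = sum(1 for q, c in pairs if q >= thr and not c)
        rows.append((thr, nc, nd))
    frame = pd.DataFrame(rows, columns=["min_mapq", "n_concordant", "n_discordant"])
    frame.attrs["n_excluded"] = n_excluded
    return frame


# ---------------------------------------------------------------------------
# pipeline summary


def run_pipeline_report(
    eval_report: Optional[EvalReport] = None,
    meth_frame: Optional[pd.DataFrame] = None,
    category_frame: Optional[pd.DataFrame] = None,
    dmc_count: Optional[int] = None,
    dmr_count: Optional[int] = None,
) -> tuple[dict, str]:
    """Aggregate stage outputs into one structured summary.

    Returns (summary dict, plain-text rendering).  Missing stages leave
    explicit null entries rather than being dropped.
    """
    summary: dict = {
        "mapping": None,
        "methylation": None,
        "categories": None,
        "differential": None,
    }
    if eval_report is not None:
        summary["mapping"] = {
            "total_reads": eval_report.total,
            "mapped": eval_report.n_correct + eval_report.n_wrong,
            "mapping_rate": (
                (eval_report.n_correct + eval_report.n_wrong) / eval_report.total
                if eval_report.total else 0.0
            ),
            **eval_report.to_dict(),
        }
    if meth_frame is not None:
        per_context = {}
        per_chrom = {}
        for ctx, grp in meth_frame.groupby("context"):
            cov = (grp["count_C"] + grp["count_T"]).sum()
            per_context[ctx] = {
                "n_sites": int(len(grp)),
                "global_ml": float(100.0 * grp["count_C"].sum() / cov) if cov else None,
            }
        for chrom, grp in meth_frame.groupby("chrom"):
            per_chrom[chrom] = {"n_sites": int(len(grp))}
        summary["methylation"] = {
            "n_sites": int(len(meth_frame)),
            "per_context": per_context,
            "per_chrom": per_chrom,
        }
    if category_frame is not None:
        summary["categories"] = {
            f"{r.context}:{r.category}": int(r.n_sites)
            for r in category_frame.itertuples(index=False)
        }
    if dmc_count is not None or dmr_count is not None:
        summary["differential"] = {"n_dmc": dmc_count, "n_dmr": dmr_count}
    lines = ["pybsmeth run summary", "=" * 22]
    for section, payload in summary.items():
        lines.append(f"[{section}]")
        if payload is None:
            lines.append("  (not available)")
        else:
            lines.append("  " + json.dumps(payload, sort_keys=True))
    return summary, "\n".join(lines)
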