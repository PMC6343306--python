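"""Bisulfite read alignment.

The search runs in converted space (read and genome both three-letter
converted, so conversion never counts as mismatch), while scoring and
mismatch counting run on the original sequences under the asymmetric
bisulfite rule: in C->T space a read T over a reference C is a match but
a read C over a reference T is a mismatch (and symmetrically G/A in the
minus-strand view).

Stages: orientation/conversion of the read, long-seed candidate search
(75 bp, up to 5 mismatches and 1 gap; a gap costs the same as 1.5
mismatches), banded affine-gap extension (match +Q / mismatch -Q, gap
open 40, gap extension 6), a mismatch gate that skips gapped DP for
nearly clean reads, soft-clip realignment of long clipped tails, and a
deep-scan paired selection that maximises the pair score rather than
pairing each mate's individual best.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from .genome_index import ConvertedGenomePair, SeedIndex, c2t, g2a, revcomp
from . import samio
from .samio import SamRecord

NEG = -(1 << 40)
_N = ord("N")


@dataclass
class AlignParams:
    seed_len: int = 75
    max_mm: int = 5
    max_gap: int = 1
    max_gap_len: int = 10
    gap_open: int = 40
    gap_extend: int = 6
    mismatch_threshold: int = 2
    band: Optional[int] = None  # default 2 * max_gap_len + 8
    min_clip: int = 20
    max_insert: int = 500
    library: str = "directional"
    indels: bool = True
    max_hits: int = 20

    def band_width(self) -> int:
        return self.band if self.band is not None else 2 * self.max_gap_len + 8


@dataclass
class Read:
    id: str
    seq: str
    quals: list[int]
    mate: int = 0  # 0 = single-end

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.id}: quality/sequence length mismatch")


@dataclass
class OrientedQuery:
    """One search orientation of a read laid out in plus coordinates."""

    seq: str  # original bases, plus-strand layout
    key: str  # converted search key
    quals: list[int]  # per-base quality, same orientation as seq
    strand: str  # reported strand: + / -
    view: str  # genome view searched: c2t / g2a
    read_conv: str  # which conversion produced the key: C2T / G2A


@dataclass
class SeedHit:
    chrom: str
    pos: int  # implied plus-strand start of the whole query
    view: str
    read_conv: str
    strand: str
    cost: float  # mismatches + 1.5 per gap
    gap: Optional[tuple[str, int, int]] = None  # (type I/D, length, seed offset)
    query: Optional[OrientedQuery] = None


@dataclass
class Alignment:
    read_id: str
    chrom: str
    pos: int  # leftmost 0-based reference coordinate
    strand: str
    bs_strand: str  # C2T / G2A (converted space of the hit)
    cigar: list[tuple[str, int]]
    n_mismatch: int
    score: int
    mapq: int = 0
    aux: Optional["Alignment"] = None
    query: Optional[OrientedQuery] = field(default=None, repr=False)

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        return self.pos + self.ref_span


@dataclass
class PairedAlignment:
    a1: Optional[Alignment]
    a2: Optional[Alignment]
    insert: int
    proper: bool


# ---------------------------------------------------------------------------
# read conversion


def convert_read(read: Read, library: str = "directional", mate2: bool = False
                 ) -> list[OrientedQuery]:
    """Enumerate the search orientations of a read.

    Directional mate-1/single-end reads live in C->T space on the plus
    strand and (via reverse complement) in G->A space on the minus
    strand; mate 2 swaps the two.  Non-directional libraries search all
    four combinations.
    """
    if not read.seq:
        raise ValueError(f"{read.id}: empty read")
    seq, rc = read.seq, revcomp(read.seq)
    q_fwd, q_rev = list(read.quals), list(read.quals)[::-1]
    fwd_first = not mate2
    orients = [
        OrientedQuery(seq, c2t(seq), q_fwd, "+", "c2t", "C2T"),
        OrientedQuery(rc, g2a(rc), q_rev, "-", "g2a", "G2A"),
    ]
    if mate2:
        orients = [
            OrientedQuery(seq, g2a(seq), q_fwd, "+", "g2a", "G2A"),
            OrientedQuery(rc, c2t(rc), q_rev, "-", "c2t", "C2T"),
        ]
    if library == "non_directional":
        extra = [
            OrientedQuery(seq, g2a(seq), q_fwd, "+", "g2a", "G2A"),
            OrientedQuery(rc, c2t(rc), q_rev, "-", "c2t", "C2T"),
        ] if fwd_first else [
            OrientedQuery(seq, c2t(seq), q_fwd, "+", "c2t", "C2T"),
            OrientedQuery(rc, g2a(rc), q_rev, "-", "g2a", "G2A"),
        ]
        orients += extra
    return orients


# ---------------------------------------------------------------------------
# seed search


def _mismatch_cum(key: np.ndarray, view: np.ndarray, diag: int) -> np.ndarray:
    """Cumulative mismatch counts of key laid on the view at offset diag."""
    L = len(key)
    seg = np.full(L, _N, dtype=np.uint8)
    lo, hi = max(0, diag), min(len(view), diag + L)
    if hi > lo:
        seg[lo - diag : hi - diag] = view[lo:hi]
    mm = (seg != key) | (seg == _N) | (key == _N)
    out = np.empty(L + 1, dtype=np.int64)
    out[0] = 0
    np.cumsum(mm, out=out[1:])
    return out


def _verify_candidate(
    key: np.ndarray,
    view: np.ndarray,
    g0: int,
    max_mm: int,
    max_gap: int,
    max_gap_len: int,
) -> Optional[tuple[int, float, Optional[tuple[str, int, int]]]]:
    """Best one-gap-or-less placement of the seed near diagonal g0.

    Returns (start, cost, gap) with cost = mismatches + 1.5 per gap, or
    None when nothing fits the mismatch/gap budget.
    """
    L = len(key)
    cums: dict[int, np.ndarray] = {}

    def cum(d: int) -> np.ndarray:
        if d not in cums:
            cums[d] = _mismatch_cum(key, view, d)
        return cums[d]

    best: Optional[tuple[int, float, Optional[tuple[str, int, int]]]] = None
    m0 = int(cum(g0)[L])
    if m0 <= max_mm:
        best = (g0, float(m0), None)
    if max_gap < 1 or (best is not None and best[1] <= 1.5):
        return best
    for d in range(1, max_gap_len + 1):
        # deletion of d reference bases: prefix on diag s, suffix on s + d
        for s in (g0, g0 - d):
            a, b = cum(s), cum(s + d)
            tot = a[1 : L] + (b[L] - b[1 : L])
            j = int(np.argmin(tot))
            mm = int(tot[j])
            if mm <= max_mm:
                cand = (s, mm + 1.5, ("D", d, j + 1))
                if best is None or cand[1] < best[1] or (
                    cand[1] == best[1] and cand[0] < best[0]
                ):
                    best = cand
        # insertion of d read bases at offset j: suffix maps to diag s - d
        if d >= L:
            continue
        for s in (g0, g0 + d):
            a, b = cum(s), cum(s - d)
            hi = L - d
            tot = a[1:hi] + (b[L] - b[1 + d : hi + d])
            if len(tot) == 0:
                continue
            j = int(np.argmin(tot))
            mm = int(tot[j])
            if mm <= max_mm:
                cand = (s, mm + 1.5, ("I", d, j + 1))
                if best is None or cand[1] < best[1] or (
                    cand[1] == best[1] and cand[0] < best[0]
                ):
                    best = cand
    return best


def _seed_search(
    oq: OrientedQuery,
    index: SeedIndex,
    params: AlignParams,
    key_offset: int = 0,
) -> list[SeedHit]:
    """Candidate hits for the seed starting at key_offset in the query."""
    key = oq.key[key_offset : key_offset + params.seed_len]
    L = len(key)
    k = index.k
    if L < k:
        return []
    budget = params.max_mm if L >= params.seed_len else int(params.max_mm * L / params.seed_len)
    key_arr = np.frombuffer(key.encode("ascii"), dtype=np.uint8)
    cand: set[tuple[str, int]] = set()
    for c in range(0, L - k + 1, k):
        kmer = key[c : c + k]
        if "N" in kmer:
            continue
        for chrom, pos in index.kmer_positions(kmer, oq.view):
            cand.add((chrom, pos - c))
    hits: dict[tuple[str, int], SeedHit] = {}
    for chrom, g0 in sorted(cand, key=lambda x: (index.chrom_index[x[0]], x[1])):
        view = index.pair.view_bytes(oq.view, chrom)
        res = _verify_candidate(
            key_arr, view, g0, budget, params.max_gap, params.max_gap_len
        )
        if res is None:
            continue
        start, cost, gap = res
        start -= key_offset
        prev = hits.get((chrom, start))
        if prev is None or cost < prev.cost:
            hits[(chrom, start)] = SeedHit(
                chrom, start, oq.view, oq.read_conv, oq.strand, cost, gap, oq
            )
    out = sorted(
        hits.values(), key=lambda h: (h.cost, index.chrom_index[h.chrom], h.pos)
    )
    return out[: params.max_hits]


def seed_align(oq: OrientedQuery, index: SeedIndex, params: AlignParams) -> list[SeedHit]:
    """Long-seed candidate search over the leading seed of the query."""
    return _seed_search(oq, index, params)


def multi_seed(oq: OrientedQuery, index: SeedIndex, params: AlignParams) -> list[SeedHit]:
    """Nonoverlapping-seed search for reads longer than 150 bp.

    Each full seed window is searched independently; hit positions are
    shifted back to the implied query start and near-duplicates (within
    the maximum gap length) are merged keeping the lowest cost.
    """
    merged: list[SeedHit] = []
    for off in range(0, len(oq.key) - params.seed_len + 1, params.seed_len):
        for hit in _seed_search(oq, index, params, key_offset=off):
            dup = None
            for other in merged:
                if other.chrom == hit.chrom and abs(other.pos - hit.pos) <= params.max_gap_len:
                    dup = other
                    break
            if dup is None:
                merged.append(hit)
            elif hit.cost < dup.cost:
                merged.remove(dup)
                merged.append(hit)
    merged.sort(key=lambda h: (h.cost, index.chrom_index[h.chrom], h.pos))
    return merged[: params.max_hits]


def find_candidates(oq: OrientedQuery, index: SeedIndex, params: AlignParams) -> list[SeedHit]:
    if len(oq.key) > 2 * params.seed_len:
        return multi_seed(oq, index, params)
    return seed_align(oq, index, params)


# ---------------------------------------------------------------------------
# extension


def bs_match(ref_base: str, read_base: str, view: str) -> bool:
    """Asymmetric bisulfite-aware base match."""
    if ref_base == "N" or read_base == "N":
        return False
    if ref_base == read_base:
        return True
    if view == "c2t":
        return ref_base == "C" and read_base == "T"
    return ref_base == "G" and read_base == "A"


def extend_ungapped(
    oq: OrientedQuery, ref: str, start: int, params: AlignParams
) -> Optional[Alignment]:
    """Gap-free diagonal alignment of the full query at ``start``.

    Returns an all-M alignment (untrimmed) with the full-length mismatch
    count, used both as the cheap extension and as the indel-gate
    evidence.  None if the query falls outside the chromosome.
    """
    n = len(oq.seq)
    if start < 0 or start + n > len(ref):
        return None
    window = ref[start : start + n]
    score = 0
    n_mm = 0
    for i in range(n):
        if bs_match(window[i], oq.seq[i], oq.view):
            score += oq.quals[i]
        else:
            score -= oq.quals[i]
            n_mm += 1
    return Alignment(
        read_id="", chrom="", pos=start, strand=oq.strand, bs_strand=oq.read_conv,
        cigar=[("M", n)], n_mismatch=n_mm, score=score, query=oq,
    )


def _banded_dp(
    read: str,
    quals: list[int],
    window: str,
    view: str,
    open_pen: int,
    ext_pen: int,
    band: int,
    d0: int,
) -> Optional[tuple[int, list[tuple[str, int]], int, int, bool]]:
    """Glocal (read-global, reference-free-ends) banded affine DP.

    Returns (score, cigar ops, start col, n_mismatch, touched_band_edge)
    or None when no cell is reachable.
    """
    n, m = len(read), len(window)
    if n == 0 or m == 0:
        return None
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (D, consumes ref)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (I, consumes read)
    for j in range(m + 1):
        M[0][j] = 0
    go_ge = open_pen + ext_pen
    for i in range(1, n + 1):
        jlo = max(1, i + d0 - band)
        jhi = min(m, i + d0 + band)
        if jlo > jhi:
            continue
        qi = quals[i - 1]
        rb = read[i - 1]
        Mi, Ei, Fi = M[i], E[i], F[i]
        Mp, Ep, Fp = M[i - 1], E[i - 1], F[i - 1]
        if i + d0 - band <= 0:
            # column 0 carries leading insertions (no reference consumed)
            Fi[0] = max(Mp[0] - go_ge, Fp[0] - ext_pen)
        for j in range(jlo, jhi + 1):
            s = qi if bs_match(window[j - 1], rb, view) else -qi
            prev = Mp[j - 1]
            if Ep[j - 1] > prev:
                prev = Ep[j - 1]
            if Fp[j - 1] > prev:
                prev = Fp[j - 1]
            if prev > NEG:
                Mi[j] = prev + s
            e_open = Mi[j - 1] - go_ge
            e_ext = Ei[j - 1] - ext_pen
            Ei[j] = e_open if e_open >= e_ext else e_ext
            f_open = Mp[j] - go_ge
            f_ext = Fp[j] - ext_pen
            Fi[j] = f_open if f_open >= f_ext else f_ext
    # best end: read fully consumed; prefer M over F, then smallest j
    best, bj, bstate = NEG, -1, "M"
    for j in range(0, m + 1):
        if M[n][j] > best:
            best, bj, bstate = M[n][j], j, "M"
        if F[n][j] > best:
            best, bj, bstate = F[n][j], j, "F"
    if bj < 0 or best <= NEG // 2:
        return None
    # traceback
    ops: list[str] = []
    i, j, state = n, bj, bstate
    touched = False
    n_mm = 0
    while i > 0:
        if abs(j - i - d0) >= band:
            touched = True
        if state == "M":
            s = quals[i - 1] if bs_match(window[j - 1], read[i - 1], view) else -quals[i - 1]
            if s < 0:
                n_mm += 1
            prev_val = M[i][j] - s
            ops.append("M")
            i, j = i - 1, j - 1
            if M[i][j] == prev_val:
                state = "M"
            elif E[i][j] == prev_val:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if E[i][j] == E[i][j - 1] - ext_pen:
                state = "E"
            else:
                state = "M"
            j -= 1
        else:  # F
            ops.append("I")
            if F[i][j] == F[i - 1][j] - ext_pen:
                state = "F"
            else:
                state = "M"
            i -= 1
    start_col = j
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return int(best), cigar, start_col, n_mm, touched


def extend_hit(
    oq: OrientedQuery,
    ref: str,
    start_guess: int,
    params: AlignParams,
    band: Optional[int] = None,
) -> Optional[Alignment]:
    """Banded affine-gap extension of the full query around a seed hit.

    The DP is global in the read with free reference ends; match scores
    +Q and mismatch -Q at the base's Phred value, the first gap base
    costs open+extend and each further base costs extend.  If the
    optimal path touches the band edge the band is widened once, after
    which the hit is dropped.
    """
    band = band if band is not None else params.band_width()
    for attempt_band in (band, band * 2):
        pad = attempt_band
        w0 = max(0, start_guess - pad)
        w1 = min(len(ref), start_guess + len(oq.seq) + pad)
        if w1 <= w0:
            return None
        window = ref[w0:w1]
        d0 = start_guess - w0
        res = _banded_dp(
            oq.seq, oq.quals, window, oq.view,
            params.gap_open, params.gap_extend, attempt_band, d0,
        )
        if res is None:
            return None
        score, cigar, start_col, n_mm, touched = res
        if not touched:
            return Alignment(
                read_id="", chrom="", pos=w0 + start_col, strand=oq.strand,
                bs_strand=oq.read_conv, cigar=cigar, n_mismatch=n_mm,
                score=score, query=oq,
            )
    return None


def _trim_from_columns(aln: Alignment, cols, params: AlignParams) -> Optional[Alignment]:
    oq = aln.query
    deltas: list[int] = []
    prev_op = None
    match_flags: list[bool] = []
    for op, qpos, rpos in cols:
        if op == "M":
            ref_base = aln._ref_seq[rpos] if rpos < len(aln._ref_seq) else "N"
            m = bs_match(ref_base, oq.seq[qpos], oq.view)
            deltas.append(oq.quals[qpos] if m else -oq.quals[qpos])
            match_flags.append(m)
        elif op in "ID":
            cost = params.gap_extend if prev_op == op else params.gap_open + params.gap_extend
            deltas.append(-cost)
            match_flags.append(True)
        else:  # S from a previous trim: zero contribution
            deltas.append(0)
            match_flags.append(True)
        prev_op = op
    # Kadane restricted to segments starting/ending on M columns
    best_sum, best_lo, best_hi = 0, -1, -1
    run_sum, run_lo = 0, None
    for idx, (colinfo, delta) in enumerate(zip(cols, deltas)):
        op = colinfo[0]
        if run_lo is None:
            if op != "M":
                continue
            run_lo, run_sum = idx, 0
        run_sum += delta
        if op == "M" and run_sum > best_sum:
            best_sum, best_lo, best_hi = run_sum, run_lo, idx
        if run_sum < 0:
            run_lo = None
    if best_lo < 0 or best_sum <= 0:
        return None
    kept = cols[best_lo : best_hi + 1]
    lead_clip = sum(1 for op, q, r in cols[:best_lo] if op in "MIS")
    tail_clip = sum(1 for op, q, r in cols[best_hi + 1 :] if op in "MIS")
    new_pos = kept[0][2]
    cigar: list[tuple[str, int]] = []
    if lead_clip:
        cigar.append(("S", lead_clip))
    for op, qpos, rpos in kept:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    if tail_clip:
        cigar.append(("S", tail_clip))
    n_mm = sum(
        1
        for (op, qpos, rpos) in kept
        if op == "M"
        and not bs_match(
            aln._ref_seq[rpos] if rpos < len(aln._ref_seq) else "N",
            aln.query.seq[qpos],
            aln.query.view,
        )
    )
    return replace(aln, pos=new_pos, cigar=cigar, n_mismatch=n_mm, score=int(best_sum))


def _attach_ref(aln: Optional[Alignment], ref: str) -> Optional[Alignment]:
    if aln is not None:
        aln._ref_seq = ref  # transient, used by trimming
    return aln


def finalize_alignment(aln: Alignment, params: AlignParams) -> Optional[Alignment]:
    """Apply soft-clip trimming to an extended alignment."""
    cols = []
    qpos, rpos = 0, aln.pos
    for op, length in aln.cigar:
        for _ in range(length):
            if op == "M":
                cols.append(("M", qpos, rpos))
                qpos += 1
                rpos += 1
            elif op == "I":
                cols.append(("I", qpos, rpos))
                qpos += 1
            elif op == "D":
                cols.append(("D", qpos, rpos))
                rpos += 1
            else:
                cols.append(("S", qpos, rpos))
                qpos += 1
    return _trim_from_columns(aln, cols, params)


# ---------------------------------------------------------------------------
# gating, clipping, pairing, mapq


def gate_indel(
    ungapped: Optional[Alignment],
    oq: OrientedQuery,
    ref: str,
    hit_pos: int,
    params: AlignParams,
) -> Optional[Alignment]:
    """Mismatch-gated indel detection.

    When the gap-free alignment of the read shows fewer full-length
    mismatches than the threshold, gapped DP is skipped entirely and the
    (trimmed) ungapped alignment is returned.  Otherwise the gapped
    extension runs and the better-scoring trimmed result wins.
    """
    trimmed_ungapped = None
    if ungapped is not None:
        _attach_ref(ungapped, ref)
        trimmed_ungapped = finalize_alignment(ungapped, params)
    gate_closed = (
        ungapped is not None
        and trimmed_ungapped is not None
        and ungapped.n_mismatch < params.mismatch_threshold
    )
    if gate_closed or not params.indels:
        return trimmed_ungapped
    gapped = extend_hit(oq, ref, hit_pos, params)
    trimmed_gapped = None
    if gapped is not None:
        _attach_ref(gapped, ref)
        trimmed_gapped = finalize_alignment(gapped, params)
    if trimmed_gapped is not None:
        # cheap gap extension makes multi-gap hopscotch paths profitable on
        # random sequence; cap accepted indel runs at the allowed gap count
        n_runs = sum(1 for op, _ in trimmed_gapped.cigar if op in "ID")
        if n_runs > params.max_gap:
            trimmed_gapped = None
    if trimmed_gapped is None:
        return trimmed_ungapped
    if trimmed_ungapped is None or trimmed_gapped.score > trimmed_ungapped.score:
        return trimmed_gapped
    return trimmed_ungapped


def soft_clip_realign(
    aln: Alignment, index: SeedIndex, params: AlignParams
) -> Alignment:
    """Realign a long soft-clipped tail as an auxiliary exact hit.

    Clips longer than ``min_clip`` are searched for a unique exact
    (0-mismatch) occurrence in the alignment's converted view; a unique
    hit is attached as ``aux`` so that primary plus auxiliary together
    represent the complete read.
    """
    oq = aln.query
    if oq is None or not aln.cigar:
        return aln
    clips = []
    if aln.cigar[0][0] == "S":
        clips.append((0, aln.cigar[0][1]))
    if aln.cigar[-1][0] == "S":
        clips.append((len(oq.seq) - aln.cigar[-1][1], aln.cigar[-1][1]))
    best_aux = None
    for qstart, length in clips:
        if length <= params.min_clip:
            continue
        key = oq.key[qstart : qstart + length]
        occ = index.lookup(key, oq.view)
        if len(occ) != 1:
            continue
        chrom, pos = occ[0]
        score = sum(oq.quals[qstart : qstart + length])
        best_aux = Alignment(
            read_id=aln.read_id, chrom=chrom, pos=pos, strand=aln.strand,
            bs_strand=aln.bs_strand, cigar=[("M", length)], n_mismatch=0,
            score=score, mapq=aln.mapq, query=oq,
        )
        best_aux._clip_qstart = qstart
        break
    return replace(aln, aux=best_aux) if best_aux is not None else aln


def compute_mapq(best: Alignment, second_best_score: Optional[int]) -> int:
    """Mapping quality from the score gap to the runner-up hit.

    A hit with no scoring alternative gets 60; co-optimal hits get 0;
    otherwise the quality scales with the score gap normalised by the
    mean base quality, capped at 60.
    """
    if second_best_score is None:
        return 60
    gap = best.score - second_best_score
    if gap <= 0:
        return 0
    quals = best.query.quals if best.query is not None else [30]
    mean_q = max(1.0, sum(quals) / len(quals))
    return max(0, min(60, round(0.4 * gap / mean_q)))


def deep_scan_pair(
    hits1: list[Alignment],
    hits2: list[Alignment],
    max_insert: int = 500,
    chrom_order: Optional[dict[str, int]] = None,
) -> PairedAlignment:
    """Select the jointly best proper pair from both candidate lists.

    A proper pair sits on one chromosome in FR orientation on opposite
    strands with outer insert size at most ``max_insert``.  When no
    proper pair exists, the individually best hits are reported with
    proper=False.
    """
    order = chrom_order or {}

    def sort_key(a: Alignment):
        return (-a.score, a.n_mismatch, order.get(a.chrom, 0), a.pos, a.strand)

    if not hits1 and not hits2:
        return PairedAlignment(None, None, 0, False)
    if not hits1 or not hits2:
        one = sorted(hits1 or hits2, key=sort_key)[0]
        return PairedAlignment(one if hits1 else None, one if hits2 else None, 0, False)
    best_pair = None
    best_total = None
    for a1 in hits1:
        for a2 in hits2:
            if a1.chrom != a2.chrom or a1.strand == a2.strand:
                continue
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            if fwd.pos > rev.pos:
                continue
            insert = rev.end - fwd.pos
            if insert > max_insert:
                continue
            total = a1.score + a2.score
            key = (-total, order.get(a1.chrom, 0), a1.pos, a2.pos)
            if best_total is None or key < best_total:
                best_total = key
                best_pair = (a1, a2, insert)
    if best_pair is not None:
        a1, a2, insert = best_pair
        signed = insert if a1.strand == "+" else -insert
        return PairedAlignment(a1, a2, signed, True)
    b1 = sorted(hits1, key=sort_key)[0]
    b2 = sorted(hits2, key=sort_key)[0]
    return PairedAlignment(b1, b2, 0, False)


# ---------------------------------------------------------------------------
# orchestration


def _align_single(
    read: Read, index: SeedIndex, params: AlignParams, mate2: bool = False
) -> list[Alignment]:
    """All valid trimmed candidate alignments of one read, best first."""
    alns: dict[tuple[str, int, str], Alignment] = {}
    for oq in convert_read(read, params.library, mate2=mate2):
        hits = find_candidates(oq, index, params)
        for hit in hits:
            ref = index.pair.ref_seq(hit.chrom)
            ungapped = extend_ungapped(oq, ref, hit.pos, params)
            aln = gate_indel(ungapped, oq, ref, hit.pos, params)
            if aln is None:
                continue
            aln = replace(aln, read_id=read.id, chrom=hit.chrom)
            aln._ref_seq = ref
            key = (aln.chrom, aln.pos, aln.strand)
            if key not in alns or aln.score > alns[key].score:
                alns[key] = aln
    order = index.chrom_index
    out = sorted(
        alns.values(),
        key=lambda a: (-a.score, a.n_mismatch, order.get(a.chrom, 0), a.pos, a.strand),
    )
    return out


def align_read(
    read: Read, index: SeedIndex, params: AlignParams, mate2: bool = False
) -> Optional[Alignment]:
    """Best alignment of a single read with mapq and clip realignment."""
    cands = _align_single(read, index, params, mate2=mate2)
    if not cands:
        return None
    best = cands[0]
    second = cands[1].score if len(cands) > 1 else None
    best = replace(best, mapq=compute_mapq(best, second))
    best.query = cands[0].query
    best = soft_clip_realign(best, index, params)
    return best


def _phred_string(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def _sam_records_for(
    aln: Optional[Alignment],
    read: Read,
    flag_extra: int = 0,
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
) -> list[SamRecord]:
    if aln is None:
        return [
            SamRecord(
                qname=read.id, flag=samio.FLAG_UNMAPPED | flag_extra,
                seq=read.seq, qual=_phred_string(read.quals),
            )
        ]
    oq = aln.query
    flag = flag_extra | (samio.FLAG_REVERSE if aln.strand == "-" else 0)
    recs = [
        SamRecord(
            qname=read.id, flag=flag, rname=aln.chrom, pos=aln.pos,
            mapq=aln.mapq, cigar=aln.cigar_string, rnext=rnext, pnext=pnext,
            tlen=tlen, seq=oq.seq, qual=_phred_string(oq.quals),
            tags=[
                ("NM", "i", aln.n_mismatch),
                ("AS", "i", aln.score),
                ("XB", "Z", aln.bs_strand),
            ],
        )
    ]
    if aln.aux is not None:
        aux = aln.aux
        qstart = getattr(aux, "_clip_qstart", 0)
        clip_len = aux.cigar[0][1]
        recs.append(
            SamRecord(
                qname=read.id,
                flag=flag | samio.FLAG_SUPPLEMENTARY,
                rname=aux.chrom, pos=aux.pos, mapq=aln.mapq,
                cigar=aux.cigar_string,
                seq=oq.seq[qstart : qstart + clip_len],
                qual=_phred_string(oq.quals[qstart : qstart + clip_len]),
                tags=[
                    ("NM", "i", aux.n_mismatch),
                    ("AS", "i", aux.score),
                    ("XB", "Z", aux.bs_strand),
                ],
            )
        )
    return recs


def align(
    reads: Iterable[Read],
    index: SeedIndex,
    params: Optional[AlignParams] = None,
) -> Iterator[SamRecord]:
    """Align single-end reads, yielding SAM records in input order."""
    params = params or AlignParams()
    for read in reads:
        aln = align_read(read, index, params)
        yield from _sam_records_for(aln, read)


def align_paired(
    pairs: Iterable[tuple[Read, Read]],
    index: SeedIndex,
    params: Optional[AlignParams] = None,
) -> Iterator[SamRecord]:
    """Align read pairs with deep-scan pair selection."""
    params = params or AlignParams()
    order = index.chrom_index
    for r1, r2 in pairs:
        c1 = _align_single(r1, index, params, mate2=False)
        c2 = _align_single(r2, index, params, mate2=True)
        pair = deep_scan_pair(c1, c2, params.max_insert, order)
        a1, a2 = pair.a1, pair.a2
        if a1 is not None:
            a1 = replace(a1, mapq=compute_mapq(a1, _second_score(c1, a1)))
            a1 = soft_clip_realign(a1, index, params)
        if a2 is not None:
            a2 = replace(a2, mapq=compute_mapq(a2, _second_score(c2, a2)))
            a2 = soft_clip_realign(a2, index, params)
        base = samio.FLAG_PAIRED | (samio.FLAG_PROPER if pair.proper else 0)
        f1 = base | samio.FLAG_READ1
        f2 = base | samio.FLAG_READ2
        if a2 is None:
            f1 |= samio.FLAG_MATE_UNMAPPED
        elif a2.strand == "-":
            f1 |= samio.FLAG_MATE_REVERSE
        if a1 is None:
            f2 |= samio.FLAG_MATE_UNMAPPED
        elif a1.strand == "-":
            f2 |= samio.FLAG_MATE_REVERSE
        rnext1 = a2.chrom if a2 is not None else "*"
        rnext2 = a1.chrom if a1 is not None else "*"
        pnext1 = a2.pos if a2 is not None else 0
        pnext2 = a1.pos if a1 is not None else 0
        tlen = pair.insert if pair.proper else 0
        yield from _sam_records_for(a1, r1, f1, rnext1, pnext1, tlen)
        yield from _sam_records_for(a2, r2, f2, rnext2, pnext2, -tlen)


def _second_score(cands: list[Alignment], chosen: Alignment) -> Optional[int]:
    for c in cands:
        if c is not chosen:
            return c.score
    return None


# ---------------------------------------------------------------------------
# FASTQ input


def read_fastq(path) -> Iterator[Read]:
    """Parse a (possibly gzipped) FASTQ file into Read objects."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            yield Read(header[1:].split()[0], seq.upper(), [ord(c) - 33 for c in qual])
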