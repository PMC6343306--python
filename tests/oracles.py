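"""Independent reference implementations used only as test oracles.

These deliberately avoid importing pybsmeth internals so that they stay
independent of the code paths they check.
"""
from __future__ import annotations

import math

NEG_INF = float("-inf")


def oracle_match(ref_base: str, read_base: str, space: str) -> bool:
    if "N" in (ref_base, read_base):
        return False
    if ref_base == read_base:
        return True
    if space == "c2t":
        return ref_base == "C" and read_base == "T"
    if space == "g2a":
        return ref_base == "G" and read_base == "A"
    raise ValueError(space)


def affine_dp_score(
    read: str,
    quals: list[int],
    window: str,
    space: str = "c2t",
    gap_open: int = 40,
    gap_ext: int = 6,
) -> float:
    """Exhaustive affine-gap DP, global in the read, free reference ends.

    Match scores +Q, mismatch -Q at the base's quality; the first base
    of a gap costs gap_open + gap_ext and every further base gap_ext.
    Gaps open only from the match state.  The alignment may end in a
    match or an insertion, never a deletion.
    """
    n, m = len(read), len(window)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    I = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            if j > 0:
                s = quals[i - 1] if oracle_match(window[j - 1], read[i - 1], space) else -quals[i - 1]
                best_prev = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
                if best_prev > NEG_INF:
                    M[i][j] = best_prev + s
                D[i][j] = max(M[i][j - 1] - gap_open - gap_ext, D[i][j - 1] - gap_ext)
            I[i][j] = max(M[i - 1][j] - gap_open - gap_ext, I[i - 1][j] - gap_ext)
    return max(max(M[n]), max(I[n]))


def naive_find_all(haystack: str, needle: str) -> list[int]:
    """All exact occurrences by brute-force scan; N never matches."""
    if "N" in needle:
        return []
    out = []
    for i in range(len(haystack) - len(needle) + 1):
        window = haystack[i : i + len(needle)]
        if window == needle and "N" not in window:
            out.append(i)
    return out


def fisher_exact_oracle(c1: int, t1: int, c2: int, t2: int) -> float:
    """Two-sided Fisher's exact p by exhaustive hypergeometric enumeration."""
    r1, r2 = c1 + t1, c2 + t2
    k = c1 + c2
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = log_comb(n, k)

    def prob(x: int) -> float:
        return math.exp(log_comb(r1, x) + log_comb(r2, k - x) - denom)

    lo, hi = max(0, k - r2), min(k, r1)
    p_obs = prob(c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def bh_oracle(pvals: list[float]) -> list[float]:
    """Textbook step-up BH: q(i) = min_{j>=i} m * p(j) / j on sorted ps."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    qs = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, m * pvals[i] / rank)
        qs[i] = min(1.0, running)
    return qs


def overlap_counts_oracle(
    sites: list[tuple[str, int]], features: list[tuple[str, int, int, str]]
) -> dict[str, int]:
    """Quadratic per-site interval scan: class -> number of sites hit."""
    out: dict[str, int] = {}
    labels = {f[3] for f in features}
    for label in labels:
        n = 0
        for chrom, pos in sites:
            if any(
                fc == chrom and fs <= pos < fe
                for fc, fs, fe, fl in features
                if fl == label
            ):
                n += 1
        out[label] = n
    return out
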