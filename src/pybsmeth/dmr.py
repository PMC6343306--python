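"""Differential methylation: Fisher's exact test without replicates,
a beta-binomial likelihood-ratio test with replicates, window validity
criteria, Benjamini-Hochberg FDR and the methylation-difference call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .region_meth import Region, sliding_windows

_EPS = 1e-6


@dataclass
class SampleMeth:
    """One condition: a label plus per-replicate site tables.

    Each replicate table is a DataFrame with chrom/pos/strand/context/
    count_C/count_T columns (the methylation caller's output).
    """

    label: str
    replicates: list[pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"sample {self.label!r} has no replicates")

    def site_frame(self) -> pd.DataFrame:
        """Wide frame keyed by site with c{i}/n{i} columns per replicate."""
        keys = ["chrom", "pos", "strand", "context"]
        out: Optional[pd.DataFrame] = None
        for i, rep in enumerate(self.replicates):
            cov = rep["count_C"] + rep["count_T"]
            part = rep[keys].copy()
            part[f"c{i}"] = rep["count_C"].to_numpy()
            part[f"n{i}"] = cov.to_numpy()
            part = part.set_index(keys)
            out = part if out is None else out.join(part, how="outer")
        out = out.fillna(0).astype(int)
        return out

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass
class DMCResult:
    chrom: str
    pos: int
    strand: str
    context: str
    p: float
    q: float = 1.0
    meth_diff: float = 0.0  # condition2 - condition1 on the 0-1 scale
    significant: bool = False


@dataclass
class DMRWindow:
    region: Region
    n_valid_a: int
    n_valid_b: int
    counts_a: tuple[int, int]  # pooled (C, coverage)
    counts_b: tuple[int, int]
    p: float
    q: float = 1.0
    meth_diff: float = 0.0
    significant: bool = False


# ---------------------------------------------------------------------------
# tests


def fisher_dmc(c1: int, t1: int, c2: int, t2: int) -> float:
    """Two-sided Fisher's exact p-value on [[c1, t1], [c2, t2]].

    Zero row margins make the test undefined and return 1.
    """
    if min(c1, t1, c2, t2) < 0:
        raise ValueError("negative counts")
    if c1 + t1 == 0 or c2 + t2 == 0:
        return 1.0
    return float(stats.fisher_exact([[c1, t1], [c2, t2]], alternative="two-sided")[1])


def _bb_loglik(mu: float, phi: float, cs: np.ndarray, ns: np.ndarray) -> float:
    mu = min(max(mu, _EPS), 1 - _EPS)
    phi = min(max(phi, _EPS), 1 - _EPS)
    r = (1 - phi) / phi
    return float(stats.betabinom.logpmf(cs, ns, mu * r, (1 - mu) * r).sum())


def _fit_mu(phi: float, cs: np.ndarray, ns: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood mean at fixed dispersion; returns (mu, loglik)."""
    res = optimize.minimize_scalar(
        lambda mu: -_bb_loglik(mu, phi, cs, ns),
        bounds=(_EPS, 1 - _EPS),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def fit_betabinom(cs: Sequence[int], ns: Sequence[int]) -> tuple[float, float, float]:
    """Joint MLE of (mu, phi) for one group; returns (mu, phi, loglik)."""
    cs = np.asarray(cs, dtype=float)
    ns = np.asarray(ns, dtype=float)

    def profile(phi: float) -> float:
        _, ll = _fit_mu(phi, cs, ns)
        return -ll

    res = optimize.minimize_scalar(
        profile, bounds=(_EPS, 1 - _EPS), method="bounded", options={"xatol": 1e-8}
    )
    phi = float(res.x)
    mu, ll = _fit_mu(phi, cs, ns)
    return mu, phi, ll


def betabinom_test(
    group_a: Sequence[tuple[int, int]], group_b: Sequence[tuple[int, int]]
) -> float:
    """Beta-binomial likelihood-ratio test between two replicate groups.

    Null: one (mu, phi) for all replicates.  Alternative: separate means
    with a shared dispersion.  The statistic 2*(llAlt - llNull) is
    referred to chi-square with one degree of freedom.
    """
    ca = np.array([c for c, _ in group_a], dtype=float)
    na = np.array([n for _, n in group_a], dtype=float)
    cb = np.array([c for c, _ in group_b], dtype=float)
    nb = np.array([n for _, n in group_b], dtype=float)
    if na.sum() == 0 or nb.sum() == 0:
        return 1.0
    call = np.concatenate([ca, cb])
    nall = np.concatenate([na, nb])

    _, _, ll_null = fit_betabinom(call, nall)

    def neg_ll_alt(phi: float) -> float:
        _, lla = _fit_mu(phi, ca, na)
        _, llb = _fit_mu(phi, cb, nb)
        return -(lla + llb)

    res = optimize.minimize_scalar(
        neg_ll_alt, bounds=(_EPS, 1 - _EPS), method="bounded", options={"xatol": 1e-8}
    )
    ll_alt = -float(res.fun)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    if stat < 1e-8:
        stat = 0.0
    return float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def call_significant(
    results: Iterable, q_threshold: float = 0.05, diff_threshold: float = 0.6
) -> None:
    """Flag results with q < threshold and |meth_diff| >= diff threshold."""
    for r in results:
        r.significant = bool(r.q < q_threshold and abs(r.meth_diff) >= diff_threshold)


# ---------------------------------------------------------------------------
# window scanning


def _valid_mask(frame: pd.DataFrame, n_reps: int, n: int) -> np.ndarray:
    """Site valid iff coverage >= n in every replicate of the sample."""
    ok = np.ones(len(frame), dtype=bool)
    for i in range(n_reps):
        ok &= frame[f"n{i}"].to_numpy() >= n
    return ok


def window_scan(
    sample_a: SampleMeth,
    sample_b: SampleMeth,
    windows: Optional[Sequence[Region]] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
    window: int = 1000,
    step: int = 500,
    m: int = 5,
    n: int = 5,
    test: str = "auto",
    context: Optional[str] = None,
) -> list[DMRWindow]:
    """Test sliding or predefined windows for differential methylation.

    A window is testable only if it contains at least ``m`` valid sites
    in both samples, where a site is valid when covered by at least
    ``n`` reads in every replicate.  Counts of sites valid in both
    samples are pooled per condition (Fisher) or summed per replicate
    (beta-binomial).  Windows failing the criteria are skipped and get
    no p-value.
    """
    fa = sample_a.site_frame().reset_index()
    fb = sample_b.site_frame().reset_index()
    if context is not None:
        fa = fa[fa["context"] == context]
        fb = fb[fb["context"] == context]
    keys = ["chrom", "pos", "strand", "context"]
    joint = fa.merge(fb, on=keys, how="outer", suffixes=("_a", "_b"))
    joint = joint.fillna(0)
    ra, rb = sample_a.n_replicates, sample_b.n_replicates

    # merge only suffixes colliding column names, so fall back to the bare name
    def cols(prefix: str, count: int, suffix: str) -> list[str]:
        out = []
        for i in range(count):
            name = f"{prefix}{i}_{suffix}"
            if name not in joint.columns:
                name = f"{prefix}{i}"
            out.append(name)
        return out

    ca_cols = cols("c", ra, "a")
    na_cols = cols("n", ra, "a")
    cb_cols = cols("c", rb, "b")
    nb_cols = cols("n", rb, "b")
    valid_a = np.ones(len(joint), dtype=bool)
    for col in na_cols:
        valid_a &= joint[col].to_numpy() >= n
    valid_b = np.ones(len(joint), dtype=bool)
    for col in nb_cols:
        valid_b &= joint[col].to_numpy() >= n
    joint["_va"] = valid_a
    joint["_vb"] = valid_b

    if windows is None:
        if chrom_lengths is None:
            raise ValueError("need either windows or chrom_lengths")
        windows = [
            r
            for chrom, length in chrom_lengths.items()
            for r in sliding_windows(chrom, length, window, step)
        ]
    if len(windows) == 0:
        return []
    use_bb = test == "betabinom" or (test == "auto" and ra >= 2 and rb >= 2)
    results: list[DMRWindow] = []
    by_chrom = {c: g.sort_values("pos") for c, g in joint.groupby("chrom")}
    for region in windows:
        grp = by_chrom.get(region.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        sub = grp.iloc[lo:hi]
        if len(sub) == 0:
            continue
        va = sub["_va"].to_numpy()
        vb = sub["_vb"].to_numpy()
        n_valid_a, n_valid_b = int(va.sum()), int(vb.sum())
        if n_valid_a < m or n_valid_b < m:
            continue
        both = va & vb
        used = sub.loc[both]
        if len(used) == 0:
            continue
        ca = int(used[ca_cols].to_numpy().sum())
        na_tot = int(used[na_cols].to_numpy().sum())
        cb = int(used[cb_cols].to_numpy().sum())
        nb_tot = int(used[nb_cols].to_numpy().sum())
        if na_tot == 0 or nb_tot == 0:
            continue
        if use_bb:
            grp_a = [
                (int(used[c].sum()), int(used[nn].sum()))
                for c, nn in zip(ca_cols, na_cols)
            ]
            grp_b = [
                (int(used[c].sum()), int(used[nn].sum()))
                for c, nn in zip(cb_cols, nb_cols)
            ]
            p = betabinom_test(grp_a, grp_b)
        else:
            p = fisher_dmc(ca, na_tot - ca, cb, nb_tot - cb)
        diff = cb / nb_tot - ca / na_tot
        results.append(
            DMRWindow(region, n_valid_a, n_valid_b, (ca, na_tot), (cb, nb_tot), p,
                      meth_diff=diff)
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def dmc_scan(
    sample_a: SampleMeth,
    sample_b: SampleMeth,
    n: int = 5,
    test: str = "auto",
    context: Optional[str] = None,
) -> list[DMCResult]:
    """Site-level differential test: each cytosine is a one-site window."""
    fa = sample_a.site_frame().reset_index()
    fb = sample_b.site_frame().reset_index()
    if context is not None:
        fa = fa[fa["context"] == context]
        fb = fb[fb["context"] == context]
    keys = ["chrom", "pos", "strand", "context"]
    joint = fa.merge(fb, on=keys, how="inner", suffixes=("_a", "_b"))
    ra, rb = sample_a.n_replicates, sample_b.n_replicates

    def cols(prefix: str, count: int, suffix: str) -> list[str]:
        out = []
        for i in range(count):
            name = f"{prefix}{i}_{suffix}"
            if name not in joint.columns:
                name = f"{prefix}{i}"
            out.append(name)
        return out

    ca_cols, na_cols = cols("c", ra, "a"), cols("n", ra, "a")
    cb_cols, nb_cols = cols("c", rb, "b"), cols("n", rb, "b")
    use_bb = test == "betabinom" or (test == "auto" and ra >= 2 and rb >= 2)
    results: list[DMCResult] = []
    for _, row in joint.iterrows():
        nas = [int(row[c]) for c in na_cols]
        nbs = [int(row[c]) for c in nb_cols]
        if min(nas) < n or min(nbs) < n:
            continue
        cas = [int(row[c]) for c in ca_cols]
        cbs = [int(row[c]) for c in cb_cols]
        ca, na_tot = sum(cas), sum(nas)
        cb, nb_tot = sum(cbs), sum(nbs)
        if use_bb:
            p = betabinom_test(list(zip(cas, nas)), list(zip(cbs, nbs)))
        else:
            p = fisher_dmc(ca, na_tot - ca, cb, nb_tot - cb)
        results.append(
            DMCResult(row["chrom"], int(row["pos"]), row["strand"], row["context"],
                      p, meth_diff=cb / nb_tot - ca / na_tot)
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# output


def dmr_frame(results: Sequence[DMRWindow]) -> pd.DataFrame:
    rows = [
        (r.region.chrom, r.region.start, r.region.end, r.n_valid_a, r.n_valid_b,
         r.counts_a[0], r.counts_a[1], r.counts_b[0], r.counts_b[1],
         r.p, r.q, r.meth_diff, r.significant)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_valid_a", "n_valid_b",
        "c_a", "cov_a", "c_b", "cov_b", "p", "q", "meth_diff", "significant",
    ])


def dmc_frame(results: Sequence[DMCResult]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.context, r.p, r.q, r.meth_diff, r.significant)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "strand", "context", "p", "q", "meth_diff", "significant",
    ])
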