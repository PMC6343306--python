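"""Region-level methylation: sliding windows, gene meta-profiles,
five-category level partition and feature annotation of cytosines.

All functions consume the per-site table produced by the methylation
caller as a pandas DataFrame (columns chrom/pos/strand/context/count_C/
count_T/...).  Region methylation pools raw counts: total sequenced Cs
over total sequenced Cs plus Ts across qualifying sites, as a
percentage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("M", "Mh", "H", "hU", "U")


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = "window"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")


def region_ml(
    df: pd.DataFrame, region: Region, min_cov: int = 0, context: Optional[str] = None,
    strand: Optional[str] = None,
) -> Optional[float]:
    """Pooled methylation percentage of one region, or None if no site."""
    sel = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] < region.end)
    )
    if context is not None:
        sel &= df["context"] == context
    if strand is not None:
        sel &= df["strand"] == strand
    sub = df.loc[sel]
    cov = sub["count_C"] + sub["count_T"]
    sub = sub.loc[cov > min_cov]
    denom = int((sub["count_C"] + sub["count_T"]).sum())
    if denom == 0:
        return None
    return 100.0 * float(sub["count_C"].sum()) / denom


def sliding_windows(
    chrom: str, chrom_len: int, window: int = 100_000, step: int = 50_000
) -> list[Region]:
    """Windows [k*step, k*step+window) clipped at the chromosome end."""
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    out = []
    start = 0
    while start < chrom_len:
        out.append(Region(chrom, start, min(start + window, chrom_len)))
        start += step
    return out


def window_meth(
    df: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 50_000,
    min_cov: int = 0,
    per_strand: bool = True,
) -> pd.DataFrame:
    """Sliding-window methylation, per strand when requested."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for region in sliding_windows(chrom, length, window, step):
            if per_strand:
                for strand in "+-":
                    ml = region_ml(df, region, min_cov, strand=strand)
                    rows.append((chrom, region.start, region.end, strand, ml))
            else:
                ml = region_ml(df, region, min_cov)
                rows.append((chrom, region.start, region.end, ".", ml))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "ml"])


# ---------------------------------------------------------------------------
# gene meta-profiles


@dataclass
class MetaProfile:
    """Mean methylation per bin over upstream flank, body and downstream."""

    values: np.ndarray  # length 3 * bins, percent or NaN
    n_sites: np.ndarray  # contributing cytosines per bin
    bins: int

    @property
    def segments(self) -> dict[str, np.ndarray]:
        b = self.bins
        return {
            "upstream": self.values[:b],
            "body": self.values[b : 2 * b],
            "downstream": self.values[2 * b :],
        }


def _bin_sums(
    df: pd.DataFrame, chrom: str, start: float, end: float, bins: int, min_cov: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin (sum C, sum C+T, n sites) for one segment."""
    sumC = np.zeros(bins)
    sumCT = np.zeros(bins)
    nsites = np.zeros(bins)
    if end <= start:
        return sumC, sumCT, nsites
    sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    if sub.empty:
        return sumC, sumCT, nsites
    cov = (sub["count_C"] + sub["count_T"]).to_numpy()
    keep = cov > min_cov
    if not keep.any():
        return sumC, sumCT, nsites
    pos = sub["pos"].to_numpy()[keep]
    c = sub["count_C"].to_numpy()[keep]
    ct = cov[keep]
    width = (end - start) / bins
    idx = np.clip(((pos - start) / width).astype(int), 0, bins - 1)
    np.add.at(sumC, idx, c)
    np.add.at(sumCT, idx, ct)
    np.add.at(nsites, idx, 1)
    return sumC, sumCT, nsites


def gene_profile(
    genes: Sequence[Region],
    df: pd.DataFrame,
    flank: int = 2000,
    bins: int = 50,
    min_cov: int = 0,
    context: Optional[str] = None,
) -> tuple[MetaProfile, pd.DataFrame]:
    """Aggregate meta-profile and per-gene bin matrix.

    Each gene contributes an upstream flank, a length-normalised body
    and a downstream flank of ``bins`` bins each; minus-strand genes are
    flipped so bin 0 is always biologically upstream.  The aggregate is
    the across-gene mean of per-gene bin levels.
    """
    if context is not None:
        df = df[df["context"] == context]
    n_bins_total = 3 * bins
    per_gene = np.full((len(genes), n_bins_total), np.nan)
    n_sites_total = np.zeros(n_bins_total)
    names = []
    for gi, gene in enumerate(genes):
        names.append(f"{gene.chrom}:{gene.start}-{gene.end}({gene.strand})")
        if gene.strand == "-":
            segs = [
                (gene.end, gene.end + flank, True),      # upstream (flipped)
                (gene.start, gene.end, True),            # body
                (gene.start - flank, gene.start, True),  # downstream
            ]
        else:
            segs = [
                (gene.start - flank, gene.start, False),
                (gene.start, gene.end, False),
                (gene.end, gene.end + flank, False),
            ]
        for si, (s, e, flip) in enumerate(segs):
            sumC, sumCT, nsites = _bin_sums(df, gene.chrom, s, e, bins, min_cov)
            if flip:
                sumC, sumCT, nsites = sumC[::-1], sumCT[::-1], nsites[::-1]
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(sumCT > 0, 100.0 * sumC / np.maximum(sumCT, 1), np.nan)
            sl = slice(si * bins, (si + 1) * bins)
            per_gene[gi, sl] = vals
            n_sites_total[sl] += nsites
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        agg = np.nanmean(per_gene, axis=0) if len(genes) else np.full(n_bins_total, np.nan)
    matrix = pd.DataFrame(per_gene, index=names)
    return MetaProfile(agg, n_sites_total, bins), matrix


# ---------------------------------------------------------------------------
# category partition


def categorize_ml(ml: float) -> str:
    """Five-category methylation partition.

    M: >80, Mh: (60,80], H: (40,60], hU: [20,40], U: <20 — upper bounds
    inclusive so every value in [0,100] maps to exactly one class.
    """
    if not 0 <= ml <= 100:
        raise ValueError(f"methylation level out of range: {ml}")
    if ml > 80:
        return "M"
    if ml > 60:
        return "Mh"
    if ml > 40:
        return "H"
    if ml >= 20:
        return "hU"
    return "U"


def category_table(df: pd.DataFrame, min_cov: int = 0) -> pd.DataFrame:
    """Counts of sites per category, per context."""
    cov = df["count_C"] + df["count_T"]
    sub = df[(cov > min_cov) & df["ml"].notna()]
    rows = []
    for context, grp in sub.groupby("context"):
        cats = grp["ml"].map(categorize_ml)
        counts = cats.value_counts()
        for cat in CATEGORIES:
            rows.append((context, cat, int(counts.get(cat, 0))))
    return pd.DataFrame(rows, columns=["context", "category", "n_sites"])


# ---------------------------------------------------------------------------
# feature annotation


def annotate_sites(
    sites: pd.DataFrame, features: Sequence[Region]
) -> pd.DataFrame:
    """Per-feature-class site counts and proportions (overlap semantics).

    A site overlapping features of several classes is counted for each
    class.  Lookup merges the intervals of each class and uses a sorted
    sweep (searchsorted) per chromosome.
    """
    total = len(sites)
    classes = sorted({f.label for f in features})
    rows = []
    for label in classes:
        merged: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            if f.label == label:
                merged.setdefault(f.chrom, []).append((f.start, f.end))
        count = 0
        for chrom, ivals in merged.items():
            ivals.sort()
            flat: list[tuple[int, int]] = []
            for s, e in ivals:
                if flat and s <= flat[-1][1]:
                    flat[-1] = (flat[-1][0], max(flat[-1][1], e))
                else:
                    flat.append((s, e))
            starts = np.array([s for s, _ in flat])
            ends = np.array([e for _, e in flat])
            pos = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
            if len(pos) == 0:
                continue
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            count += int(ok.sum())
        rows.append((label, count, count / total if total else 0.0))
    return pd.DataFrame(rows, columns=["feature", "n_sites", "proportion"])


# ---------------------------------------------------------------------------
# feature file input


def load_bed(path, label: str = "window") -> list[Region]:
    """BED3/BED6 intervals as Regions (name column becomes the label)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else label
            strand = parts[5] if len(parts) > 5 else "."
            out.append(Region(chrom, start, end, strand, name))
    return out


def load_gtf_genes(path) -> list[Region]:
    """Gene records from a GTF file as strand-aware Regions."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] != "gene":
                continue
            out.append(
                Region(parts[0], int(parts[3]) - 1, int(parts[4]), parts[6], "gene")
            )
    return out


def promoters(genes: Sequence[Region], flank: int = 2000) -> list[Region]:
    """Strand-aware promoter regions: ``flank`` bp upstream of the TSS."""
    out = []
    for g in genes:
        if g.strand == "-":
            out.append(Region(g.chrom, g.end, g.end + flank, g.strand, "promoter"))
        else:
            start = max(0, g.start - flank)
            if start < g.start:
                out.append(Region(g.chrom, start, g.start, g.strand, "promoter"))
    return out
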