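"""Genome loading, bisulfite-converted views, seed indexing and RRBS digestion.

All coordinates are 0-based, half-open.  SAM emission converts to 1-based
on output only.  The two converted views share the plus-strand coordinate
system: the minus-strand view is represented as G->A substitution on plus
coordinates rather than a reverse-complemented string, so every hit
position is natively a plus-strand position.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

INDEX_FORMAT = "pybsmeth-index"
INDEX_VERSION = 1


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMP)[::-1]


def c2t(seq: str) -> str:
    return seq.replace("C", "T")


def g2a(seq: str) -> str:
    return seq.replace("G", "A")


@dataclass
class ReferenceGenome:
    """An in-memory reference genome restricted to the A/C/G/T/N alphabet."""

    names: list[str]
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            seq = self.seqs[name]
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self.seqs[n]) for n in self.names}

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        names: list[str] = []
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs[rec.id] = str(rec.seq).upper()
        if not names:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(names, seqs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.seqs[n]), id=n, description="") for n in self.names
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class ConvertedGenomePair:
    """Plus-strand C->T view and minus-strand (G->A on plus coords) view."""

    c2t_view: dict[str, str]
    g2a_view: dict[str, str]
    source: ReferenceGenome
    _bytes_cache: dict = field(default_factory=dict, repr=False)

    def view(self, name: str) -> dict[str, str]:
        if name == "c2t":
            return self.c2t_view
        if name == "g2a":
            return self.g2a_view
        raise KeyError(name)

    def view_bytes(self, view: str, chrom: str) -> np.ndarray:
        """uint8 array of the converted view sequence, cached."""
        key = (view, chrom)
        if key not in self._bytes_cache:
            self._bytes_cache[key] = np.frombuffer(
                self.view(view)[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._bytes_cache[key]

    def ref_seq(self, chrom: str) -> str:
        return self.source.seqs[chrom]


def convert_genome(genome: ReferenceGenome) -> ConvertedGenomePair:
    """Build the two converted genome views sharing plus coordinates."""
    if not genome.names or all(len(genome.seqs[n]) == 0 for n in genome.names):
        raise ValueError("cannot convert an empty genome")
    c2t_view = {n: c2t(genome.seqs[n]) for n in genome.names}
    g2a_view = {n: g2a(genome.seqs[n]) for n in genome.names}
    return ConvertedGenomePair(c2t_view, g2a_view, genome)


@dataclass
class ReducedGenome:
    """RRBS in-silico digestion result.

    ``fragments`` are the retained (length-filtered) fragments;
    ``raw_fragments`` tile each chromosome exactly before the filter.
    """

    fragments: list[tuple[str, int, int]]
    raw_fragments: list[tuple[str, int, int]]
    enzyme_site: str
    cut_offset: int
    max_fragment_len: int

    def mask(self, genome: ReferenceGenome) -> dict[str, np.ndarray]:
        """Boolean per-position inclusion mask per chromosome."""
        out = {n: np.zeros(len(genome.seqs[n]), dtype=bool) for n in genome.names}
        for chrom, start, end in self.fragments:
            out[chrom][start:end] = True
        return out


def digest_rrbs(
    genome: ReferenceGenome,
    site: str = "CCGG",
    cut_offset: int = 1,
    max_len: int = 600,
) -> ReducedGenome:
    """Cut the plus strand at every enzyme site and keep short fragments.

    The cut is placed at ``occurrence_start + cut_offset`` (C^CGG for MspI
    is site="CCGG", cut_offset=1).  Terminal fragments are closed by the
    chromosome ends and are subject to the same length filter.
    """
    site = site.upper().replace("-", "").replace("^", "")
    if not site or set(site) - set("ACGT"):
        raise ValueError(f"recognition site must be a fixed A/C/G/T pattern: {site!r}")
    if not 0 <= cut_offset < len(site):
        raise ValueError("cut_offset outside the recognition site")
    raw: list[tuple[str, int, int]] = []
    kept: list[tuple[str, int, int]] = []
    for chrom in genome.names:
        seq = genome.seqs[chrom]
        cuts = []
        i = seq.find(site)
        while i != -1:
            cuts.append(i + cut_offset)
            i = seq.find(site, i + 1)
        bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
        for a, b in zip(bounds, bounds[1:]):
            if b <= a:
                continue
            raw.append((chrom, a, b))
            if b - a <= max_len:
                kept.append((chrom, a, b))
    return ReducedGenome(kept, raw, site, cut_offset, max_len)


class SeedIndex:
    """Exact k-mer lookup over both converted genome views.

    A hashed k-mer table maps every k-mer of each view to its plus-strand
    positions.  Queries longer than k are verified by direct comparison
    against the view, so ``lookup`` returns exact full-query matches.
    k-mers containing N are never indexed and queries containing N never
    match.
    """

    def __init__(
        self,
        pair: ConvertedGenomePair,
        seed_len: int = 12,
        regions: Optional[ReducedGenome] = None,
    ):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        shortest = min(len(s) for s in pair.source.seqs.values())
        if seed_len > shortest:
            raise ValueError(
                f"seed_len {seed_len} exceeds shortest chromosome ({shortest} bp)"
            )
        self.pair = pair
        self.k = seed_len
        self.chrom_names = list(pair.source.names)
        self.chrom_index = {n: i for i, n in enumerate(self.chrom_names)}
        self.regions = regions
        self._tables: dict[str, dict[str, list[tuple[str, int]]]] = {}
        mask = regions.mask(pair.source) if regions is not None else None
        for view in ("c2t", "g2a"):
            table: dict[str, list[tuple[str, int]]] = {}
            for chrom in self.chrom_names:
                seq = pair.view(view)[chrom]
                allowed = mask[chrom] if mask is not None else None
                for i in range(len(seq) - seed_len + 1):
                    kmer = seq[i : i + seed_len]
                    if "N" in kmer:
                        continue
                    if allowed is not None and not allowed[i : i + seed_len].all():
                        continue
                    table.setdefault(kmer, []).append((chrom, i))
            self._tables[view] = table

    def kmer_positions(self, kmer: str, view: str) -> list[tuple[str, int]]:
        """Positions of an exact k-mer (length must equal k)."""
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != index k {self.k}")
        return self._tables[view].get(kmer, [])

    def lookup(self, query: str, view: str) -> list[tuple[str, int]]:
        """All exact full-length occurrences of ``query`` in one view."""
        if len(query) < self.k or "N" in query:
            return []
        out = []
        for chrom, pos in self.kmer_positions(query[: self.k], view):
            ref = self.pair.view(view)[chrom]
            window = ref[pos : pos + len(query)]
            if window == query and "N" not in window:
                out.append((chrom, pos))
        return out

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format": INDEX_FORMAT,
            "version": INDEX_VERSION,
            "k": self.k,
            "chroms": self.chrom_names,
            "sequences": {n: self.pair.source.seqs[n] for n in self.chrom_names},
            "rrbs": None
            if self.regions is None
            else {
                "fragments": [list(f) for f in self.regions.fragments],
                "raw_fragments": [list(f) for f in self.regions.raw_fragments],
                "enzyme_site": self.regions.enzyme_site,
                "cut_offset": self.regions.cut_offset,
                "max_fragment_len": self.regions.max_fragment_len,
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "SeedIndex":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != INDEX_FORMAT:
            raise ValueError(f"{path} is not a {INDEX_FORMAT} file")
        if doc.get("version") != INDEX_VERSION:
            raise ValueError(f"unsupported index version {doc.get('version')}")
        genome = ReferenceGenome(doc["chroms"], doc["sequences"])
        pair = convert_genome(genome)
        regions = None
        if doc["rrbs"] is not None:
            r = doc["rrbs"]
            regions = ReducedGenome(
                [tuple(f) for f in r["fragments"]],
                [tuple(f) for f in r["raw_fragments"]],
                r["enzyme_site"],
                r["cut_offset"],
                r["max_fragment_len"],
            )
        return cls(pair, seed_len=doc["k"], regions=regions)


def build_index(
    pair: ConvertedGenomePair,
    seed_len: int = 12,
    regions: Optional[ReducedGenome] = None,
) -> SeedIndex:
    """Build the exact-substring seed index over both converted views."""
    return SeedIndex(pair, seed_len=seed_len, regions=regions)
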