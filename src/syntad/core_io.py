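"""Genomic-interval data model, interval arithmetic, and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs.  Strand is carried on
intervals but ignored by overlap arithmetic unless an operation says
otherwise.  Everything downstream (TAD recovery, boundary extraction,
permutation enrichment, regulatory-unit assignment) is built on the three
types here: :class:`GenomicInterval`, :class:`Genome` and :class:`Track`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Genome",
    "Track",
    "FormatError",
    "merge_intervals",
    "flatten",
    "overlap_bp",
    "complement",
    "read_bed",
    "write_bed",
    "read_tsv_table",
]

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Signed overlap in bp; <= 0 when disjoint (0 = touching)."""
        if self.chrom != other.chrom:
            return -(10**15)
        return min(self.end, other.end) - max(self.start, other.start)


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths; the rotation bound for shifts."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chroms):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_lengths(cls, lengths: dict[str, int] | Sequence[tuple[str, int]]) -> "Genome":
        items = lengths.items() if isinstance(lengths, dict) else lengths
        return cls(tuple((str(c), int(n)) for c, n in items))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for c, n in self.chroms:
            if c == chrom:
                return n
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(n for _, n in self.chroms)


@dataclass
class Track:
    """A labelled collection of intervals (a BED file in memory)."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def validate_against(self, genome: Genome) -> None:
        for iv in self.intervals:
            if iv.end > genome.length(iv.chrom):
                raise ValueError(f"{iv} exceeds chromosome length {genome.length(iv.chrom)}")

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome sorted (starts, ends) arrays, unflattened."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        arrays = {}
        for chrom, pairs in out.items():
            pairs.sort()
            arr = np.asarray(pairs, dtype=np.int64)
            arrays[chrom] = (arr[:, 0], arr[:, 1])
        return arrays

    def flattened(self) -> "Track":
        return Track(self.label, flatten(self.intervals))

    @property
    def covered_bp(self) -> int:
        return sum(iv.width for iv in flatten(self.intervals))

    def covered_bp_by_chrom(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv in flatten(self.intervals):
            out[iv.chrom] = out.get(iv.chrom, 0) + iv.width
        return out


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_overlap_bp: int
) -> list[GenomicInterval]:
    """Merge intervals whose pairwise overlap strictly exceeds ``min_overlap_bp``.

    With ``min_overlap_bp=1`` two intervals sharing exactly 1 bp stay
    separate (the 'TAD1.TAD2' touch structure survives); an overlap of
    2 bp or more merges.  With ``min_overlap_bp=0`` any >= 1 bp overlap
    merges but touching intervals stay separate.  Merging is transitive
    along the sorted order.  The result is idempotent and conserves
    covered bp.
    """
    if min_overlap_bp < 0:
        raise ValueError("min_overlap_bp must be >= 0")
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].overlap(iv) > min_overlap_bp:
            prev = out[-1]
            out[-1] = replace(prev, end=max(prev.end, iv.end), strand=".")
        else:
            out.append(iv)
    return out


def flatten(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or touching spans become one block.

    Strand is dropped (blocks are unstranded).  Idempotent and
    order-invariant.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].overlap(iv) >= 0:
            prev = out[-1]
            out[-1] = replace(prev, end=max(prev.end, iv.end), strand=".")
        elif iv.strand != ".":
            out.append(replace(iv, strand="."))
        else:
            out.append(iv)
    return out


def overlap_bp(a: Track, b: Track) -> int:
    """Total intersection, in bp, of two tracks after flattening each.

    Symmetric; strand-blind.
    """
    a_fl = a.flattened().by_chrom()
    b_fl = b.flattened().by_chrom()
    total = 0
    for chrom in set(a_fl) & set(b_fl):
        sa, ea = a_fl[chrom]
        sb, eb = b_fl[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def complement(track: Track, genome: Genome) -> Track:
    """Unstranded complement of a track within a genome."""
    blocks = track.flattened().by_chrom()
    out: list[GenomicInterval] = []
    for chrom, length in genome.chroms:
        cursor = 0
        if chrom in blocks:
            starts, ends = blocks[chrom]
            for s, e in zip(starts, ends):
                if s > cursor:
                    out.append(GenomicInterval(chrom, cursor, int(s)))
                cursor = max(cursor, int(e))
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return Track(f"complement({track.label})", out)


# ---------------------------------------------------------------------------
# plain-text IO

_BED_COLS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path: str | Path, label: str | None = None) -> Track:
    """Read a 3- or 6-column BED file into a Track.

    Malformed lines raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return Track(label or path.stem, intervals)


def write_bed(track: Track, path: str | Path, six_column: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals):
            if six_column:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.label}.{i}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tsv_table(path: str | Path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a headered TSV, optionally coercing/validating a column schema."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        missing = set(schema) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        for col, typ in schema.items():
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: column {col!r} not coercible to {typ}") from exc
    return df
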