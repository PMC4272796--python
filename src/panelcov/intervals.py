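"""Exact genomic interval algebra on 0-based half-open coordinates.

All annotation arithmetic in the coverage audit — collapsing transcripts
to unique genomic locations, nesting one annotation database inside
another, and counting unique bases — reduces to set algebra on disjoint
genomic intervals.  This module provides that algebra with BED-style
coordinate semantics: ``start`` is 0-based inclusive, ``end`` exclusive,
and an :class:`IntervalSet` is always held in canonical merged form
(sorted, pairwise disjoint, non-abutting), so ``total_bases`` is exactly
the cardinality of the underlying per-base set.

Chromosome names are opaque strings compared verbatim ("chr1" != "1");
:func:`read_bed` offers an optional normalization for mixed inputs.
Strand is ignored throughout: coverage is strandless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union


class IntervalError(ValueError):
    """An interval violates the coordinate invariants (start < end, start >= 0)."""


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the file and line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on one chromosome.

    Empty or negative ranges are rejected at construction, so every
    stored interval covers at least one base.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise IntervalError(f"non-integer coordinates in {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise IntervalError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise IntervalError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


BedRecord = tuple[GenomicInterval, Optional[str]]


@dataclass(frozen=True)
class IntervalSet:
    """A canonical disjoint collection of :class:`GenomicInterval`.

    Invariants: intervals are sorted by ``(chrom, start)``; any two
    intervals on the same chromosome are separated by a gap of at least
    one base (abutting inputs are merged at construction).  Build one
    with :func:`merge_intervals`; the algebra methods preserve the form.
    """

    intervals: tuple[GenomicInterval, ...] = ()

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_bases(self) -> int:
        """Number of distinct bases covered (sum of interval lengths)."""
        return sum(iv.end - iv.start for iv in self.intervals)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return intersect(self, other)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        return subtract(self, other)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return merge_intervals(list(self.intervals) + list(other.intervals))

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


EMPTY = IntervalSet()


def merge_intervals(raw: Iterable[GenomicInterval]) -> IntervalSet:
    """Collapse arbitrary intervals to canonical unique genomic locations.

    Overlapping and abutting intervals (``a.end == b.start``) are merged,
    so the result covers exactly the union of the input bases.
    """
    items = list(raw)
    for iv in items:
        if not isinstance(iv, GenomicInterval):
            raise IntervalError(f"not a GenomicInterval: {iv!r}")
    items.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return IntervalSet(tuple(merged))


def _per_chrom(a: IntervalSet, b: IntervalSet) -> Iterator[tuple[str, list[GenomicInterval], list[GenomicInterval]]]:
    ac, bc = a.by_chrom(), b.by_chrom()
    for chrom in sorted(set(ac) | set(bc)):
        yield chrom, ac.get(chrom, []), bc.get(chrom, [])


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in both sets (commutative)."""
    out: list[GenomicInterval] = []
    for chrom, av, bv in _per_chrom(a, b):
        i = j = 0
        while i < len(av) and j < len(bv):
            lo = max(av[i].start, bv[j].start)
            hi = min(av[i].end, bv[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if av[i].end <= bv[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(tuple(out))


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases in ``a`` and not in ``b``."""
    out: list[GenomicInterval] = []
    bc = b.by_chrom()
    for iv in a:
        cuts = bc.get(iv.chrom, [])
        lo = iv.start
        for cut in cuts:
            if cut.end <= lo or cut.start >= iv.end:
                continue
            if cut.start > lo:
                out.append(GenomicInterval(iv.chrom, lo, cut.start))
            lo = max(lo, cut.end)
            if lo >= iv.end:
                break
        if lo < iv.end:
            out.append(GenomicInterval(iv.chrom, lo, iv.end))
    return IntervalSet(tuple(out))


def total_bases(s: IntervalSet) -> int:
    return s.total_bases


def contained_fraction(subset: IntervalSet, superset: IntervalSet) -> float:
    """Fraction of the superset's bases also present in the subset.

    This is the audit's representation measure: how much of a broader
    annotation's footprint a narrower one retains.
    """
    denom = superset.total_bases
    if denom == 0:
        raise IntervalError("contained_fraction is undefined for an empty superset")
    return intersect(subset, superset).total_bases / denom


def normalize_chrom(name: str, mode: Optional[str]) -> str:
    if mode is None or mode == "none":
        return name
    if mode == "strip_chr":
        return name[3:] if name.startswith("chr") else name
    if mode == "add_chr":
        return name if name.startswith("chr") else "chr" + name
    raise ValueError(f"unknown chromosome normalization mode: {mode!r}")


def read_bed(path: Union[str, Path], *, chrom_normalize: Optional[str] = None) -> list[BedRecord]:
    """Read a 3+ column BED file into ``(interval, label)`` records.

    Column 4, when present, is kept as the record label (gene or
    transcript symbol); further columns (score, strand, ...) are
    ignored.  ``track``, ``browser`` and ``#`` comment lines are
    skipped.  Coordinates are taken verbatim as 0-based half-open.
    """
    path = Path(path)
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip():
                continue
            if stripped.startswith(("track", "browser", "#")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            chrom = normalize_chrom(fields[0], chrom_normalize)
            try:
                iv = GenomicInterval(chrom, start, end)
            except IntervalError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            label = fields[3] if len(fields) >= 4 and fields[3] != "" else None
            records.append((iv, label))
    return records


def write_bed(records: Iterable[Union[BedRecord, GenomicInterval]], path: Union[str, Path]) -> None:
    """Write ``(interval, label)`` records (or bare intervals) as BED.

    Round-trips with :func:`read_bed`: labels go to column 4; unlabeled
    records are emitted as 3 columns.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, label = rec, None
            else:
                iv, label = rec
            if label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")
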