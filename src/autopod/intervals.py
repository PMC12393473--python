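"""Genomic interval model and arithmetic on 0-based, half-open coordinates.

All operations follow BED conventions: an interval covers positions
``start .. end-1``; two intervals overlap when they share at least one
base, so abutting intervals (``a.end == b.start``) do *not* overlap.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "flatten",
    "subtract",
    "intersect_count",
    "overlaps_any",
    "flank_windows",
    "read_bed",
    "write_bed",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when ≥1 base is shared; abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def _key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``.  The set may
    contain overlapping intervals; :func:`flatten` produces the disjoint
    form.  Equality compares the interval lists only (labels are
    presentation metadata).
    """

    __slots__ = ("label", "intervals", "_by_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval._key)
        )
        self._by_chrom: dict[str, tuple[list[int], list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    def with_label(self, label: str) -> "IntervalSet":
        return IntervalSet(self.intervals, label=label)

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def covered_bp(self) -> int:
        """Number of distinct bases covered by the set."""
        return sum(len(iv) for iv in flatten(self))

    def _chrom_index(self) -> dict[str, tuple[list[int], list[int]]]:
        # sorted start / end lists per chrom, for overlap counting
        if self._by_chrom is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.intervals:
                starts, ends = idx.setdefault(iv.chrom, ([], []))
                starts.append(iv.start)
                ends.append(iv.end)
            for starts, ends in idx.values():
                ends.sort()
            self._by_chrom = idx
        return self._by_chrom

    def count_overlapping(self, iv: GenomicInterval) -> int:
        """Number of intervals in this set overlapping ``iv`` by ≥1 bp."""
        idx = self._chrom_index().get(iv.chrom)
        if idx is None:
            return 0
        starts, ends = idx
        return bisect_left(starts, iv.end) - bisect_right(ends, iv.start)

    def covers(self, chrom: str, pos: int) -> bool:
        return self.count_overlapping(GenomicInterval(chrom, pos, pos + 1)) > 0


def flatten(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge overlapping intervals into a disjoint set.

    With the default ``gap=0`` only intervals sharing ≥1 base are joined,
    so abutting intervals stay separate.  With ``gap=g`` intervals whose
    separation (``next.start − prev.end``) is strictly below ``g`` are
    also joined (``gap=1`` merges abutting intervals).
    """
    merged: list[GenomicInterval] = []
    for iv in s:
        last = merged[-1] if merged else None
        if last is not None and iv.chrom == last.chrom and iv.start < last.end + gap:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged, label=s.label)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Remove every base covered by ``b`` from ``a``.

    Intervals of ``a`` may be split into several fragments; each fragment
    keeps the name (and strand) of its parent interval so provenance
    survives masking.
    """
    mask = flatten(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in mask:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        cursor = iv.start
        for m in by_chrom.get(iv.chrom, ()):
            if m.end <= cursor:
                continue
            if m.start >= iv.end:
                break
            if m.start > cursor:
                out.append(replace(iv, start=cursor, end=m.start))
            cursor = max(cursor, m.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(replace(iv, start=cursor, end=iv.end))
    return IntervalSet(out, label=a.label)


def intersect_count(a: IntervalSet, b: IntervalSet) -> list[int]:
    """For each interval of ``a`` (in sorted order), the number of
    ``b``-intervals overlapping it by ≥1 bp."""
    return [b.count_overlapping(iv) for iv in a]


def overlaps_any(a: IntervalSet, b: IntervalSet) -> list[bool]:
    """Per interval of ``a``: does it overlap ≥1 interval of ``b``?"""
    return [n > 0 for n in intersect_count(a, b)]


def flank_windows(
    features: IntervalSet, width: int, chrom_lengths: Mapping[str, int]
) -> IntervalSet:
    """Windows of ``width`` bp on either side of each feature.

    The feature body is excluded; windows are clamped to
    ``[0, chrom length)`` and dropped entirely when empty after clamping.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out: list[GenomicInterval] = []
    for iv in features:
        if iv.chrom not in chrom_lengths:
            raise KeyError(f"unknown chrom length for {iv.chrom!r}")
        clen = chrom_lengths[iv.chrom]
        left_start = max(0, iv.start - width)
        if left_start < iv.start:
            out.append(GenomicInterval(iv.chrom, left_start, iv.start, name=iv.name))
        right_end = min(clen, iv.end + width)
        if iv.end < right_end:
            out.append(GenomicInterval(iv.chrom, iv.end, right_end, name=iv.name))
    return IntervalSet(out, label=f"{features.label}_flank{width}")


class BedParseError(ValueError):
    """Raised for malformed BED records; message carries the line number."""


def read_bed(path, label: str | None = None) -> IntervalSet:
    """Read a 3+ column BED file.

    Columns beyond the sixth are ignored; a name of ``"."`` is read as
    unset.  Malformed or inverted records raise :class:`BedParseError`
    naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected ≥3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    if label is None:
        import os

        label = os.path.splitext(os.path.basename(str(path)))[0]
    return IntervalSet(intervals, label=label)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED3 (or BED6 when any interval carries a name or strand)."""
    six = any(iv.name is not None or iv.strand != "." for iv in s)
    with open(path, "w") as fh:
        for iv in s:
            if six:
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
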