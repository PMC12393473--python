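"""Pairwise coordinate maps (chain files) and interval liftover.

A :class:`ChainMap` is a collection of gap-free alignment blocks between a
*source* and a *target* assembly.  Blocks carry a ``run_id`` grouping them
into colinear runs (one run per chain record in the UCSC dialect); a run
is the unit a query interval can map to.

Two on-disk dialects are supported and parse to identical objects:

* the UCSC chain layout (``chain score tName tSize tStrand tStart tEnd
  qName qSize qStrand qStart qEnd id`` followed by ``size dt dq`` lines);
* a simplified TSV block table (one block per row).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval

__all__ = ["ChainBlock", "ChainMap", "LiftoverResult", "liftover_interval"]

NO_COVERAGE = "no_coverage"
BELOW_MIN_MATCH = "below_min_match"
MULTIPLE_HITS = "multiple_hits"

_TSV_COLUMNS = (
    "source_chrom",
    "source_start",
    "source_end",
    "target_chrom",
    "target_start",
    "target_end",
    "target_strand",
    "run_id",
)


@dataclass(frozen=True)
class ChainBlock:
    """One colinear, equal-length aligned block.

    Target coordinates are always forward-strand; for
    ``target_strand == '-'`` the base at source position ``p`` maps to
    target position ``target_end - 1 - (p - source_start)``.
    """

    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    target_strand: str = "+"
    run_id: int = 0

    def __post_init__(self) -> None:
        if self.source_end - self.source_start != self.target_end - self.target_start:
            raise ValueError("block source and target lengths differ")
        if self.source_start < 0 or self.source_start >= self.source_end:
            raise ValueError("invalid block source coordinates")
        if self.target_strand not in ("+", "-"):
            raise ValueError(f"invalid target strand {self.target_strand!r}")

    def map_position(self, pos: int) -> int:
        """Target position of source base ``pos`` (must lie in the block)."""
        if not (self.source_start <= pos < self.source_end):
            raise ValueError("position outside block")
        if self.target_strand == "+":
            return self.target_start + (pos - self.source_start)
        return self.target_end - 1 - (pos - self.source_start)


class ChainMap:
    """A set of alignment blocks, non-overlapping on the source assembly."""

    def __init__(self, blocks: Iterable[ChainBlock], name: str = ""):
        self.name = name
        self.blocks: tuple[ChainBlock, ...] = tuple(
            sorted(blocks, key=lambda b: (b.source_chrom, b.source_start))
        )
        prev: ChainBlock | None = None
        for b in self.blocks:
            if (
                prev is not None
                and b.source_chrom == prev.source_chrom
                and b.source_start < prev.source_end
            ):
                raise ValueError(
                    f"chain blocks overlap on source at "
                    f"{b.source_chrom}:{b.source_start}"
                )
            prev = b
        self._runs: dict[int, tuple[ChainBlock, ...]] = {}
        for b in self.blocks:
            self._runs.setdefault(b.run_id, ())
        for rid in self._runs:
            self._runs[rid] = tuple(b for b in self.blocks if b.run_id == rid)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def runs(self) -> Mapping[int, tuple[ChainBlock, ...]]:
        return self._runs

    def invert(self) -> "ChainMap":
        """Swap source and target; valid when targets are non-overlapping."""
        inv = [
            ChainBlock(
                b.target_chrom,
                b.target_start,
                b.target_end,
                b.source_chrom,
                b.source_start,
                b.source_end,
                b.target_strand,
                b.run_id,
            )
            for b in self.blocks
        ]
        return ChainMap(inv, name=f"{self.name}_inverted")

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_ucsc(cls, path, name: str = "") -> "ChainMap":
        blocks: list[ChainBlock] = []
        with open(path) as fh:
            header: list[str] | None = None
            s_pos = q_pos = 0
            q_size = 0
            run_id = 0
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    header = None
                    continue
                fields = line.split()
                if fields[0] == "chain":
                    header = fields
                    s_pos = int(fields[5])
                    q_size = int(fields[8])
                    q_pos = int(fields[10])
                    run_id = int(fields[12]) if len(fields) > 12 else run_id + 1
                    continue
                if header is None:
                    raise ValueError(f"{path}: block line outside a chain record")
                size = int(fields[0])
                s_chrom, q_chrom, q_strand = header[2], header[7], header[9]
                if q_strand == "+":
                    t_start, t_end = q_pos, q_pos + size
                else:
                    t_start, t_end = q_size - (q_pos + size), q_size - q_pos
                blocks.append(
                    ChainBlock(
                        s_chrom, s_pos, s_pos + size,
                        q_chrom, t_start, t_end,
                        q_strand, run_id,
                    )
                )
                if len(fields) == 3:
                    s_pos += size + int(fields[1])
                    q_pos += size + int(fields[2])
                else:  # terminal block of the chain
                    header = None
        return cls(blocks, name=name)

    def to_ucsc(
        self,
        path,
        source_sizes: Mapping[str, int],
        target_sizes: Mapping[str, int],
    ) -> None:
        with open(path, "w") as fh:
            for rid, run in sorted(self._runs.items()):
                strand = run[0].target_strand
                if any(b.target_strand != strand for b in run):
                    raise ValueError("mixed strands within one run")
                ordered = sorted(run, key=lambda b: b.source_start)
                s_chrom, q_chrom = ordered[0].source_chrom, ordered[0].target_chrom
                q_size = target_sizes[q_chrom]

                def qpos(b: ChainBlock) -> int:
                    # start in q-strand coordinates, as the format requires
                    return b.target_start if strand == "+" else q_size - b.target_end

                s_start, s_end = ordered[0].source_start, ordered[-1].source_end
                q_start = min(qpos(b) for b in ordered)
                q_end = max(qpos(b) + (b.target_end - b.target_start) for b in ordered)
                fh.write(
                    f"chain 1000 {s_chrom} {source_sizes[s_chrom]} + "
                    f"{s_start} {s_end} {q_chrom} {q_size} {strand} "
                    f"{q_start} {q_end} {rid}\n"
                )
                for i, b in enumerate(ordered):
                    size = b.source_end - b.source_start
                    if i + 1 < len(ordered):
                        nxt = ordered[i + 1]
                        dt = nxt.source_start - b.source_end
                        dq = qpos(nxt) - (qpos(b) + size)
                        fh.write(f"{size}\t{dt}\t{dq}\n")
                    else:
                        fh.write(f"{size}\n")
                fh.write("\n")

    @classmethod
    def from_tsv(cls, path, name: str = "") -> "ChainMap":
        blocks: list[ChainBlock] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != len(_TSV_COLUMNS):
                    raise ValueError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
                blocks.append(
                    ChainBlock(
                        f[0], int(f[1]), int(f[2]),
                        f[3], int(f[4]), int(f[5]),
                        f[6], int(f[7]),
                    )
                )
        return cls(blocks, name=name)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            for b in self.blocks:
                fh.write(
                    f"{b.source_chrom}\t{b.source_start}\t{b.source_end}\t"
                    f"{b.target_chrom}\t{b.target_start}\t{b.target_end}\t"
                    f"{b.target_strand}\t{b.run_id}\n"
                )


@dataclass
class LiftoverResult:
    """Outcome of lifting one interval: mapped intervals, or a reason code
    (``no_coverage`` | ``below_min_match`` | ``multiple_hits``) when empty."""

    intervals: list[GenomicInterval]
    reason: str | None = None

    def __bool__(self) -> bool:
        return bool(self.intervals)


def liftover_interval(
    interval: GenomicInterval,
    chain: ChainMap,
    allow_multiple: bool = False,
    min_match: float = 1.0,
) -> LiftoverResult:
    """Map ``interval`` through ``chain``.

    Every colinear run is considered a candidate locus.  A run qualifies
    when at least ``min_match`` of the interval's bases fall in its
    blocks; the mapped interval is the target span of those bases.  With
    ``allow_multiple=False`` more than one qualifying run yields an empty
    result flagged ``multiple_hits``.
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    candidates: list[tuple[int, int, GenomicInterval]] = []
    any_coverage = False
    for rid, run in chain.runs.items():
        covered = 0
        t_chrom: str | None = None
        t_min = t_max = 0
        strand = "+"
        for b in run:
            if b.source_chrom != interval.chrom:
                continue
            lo = max(interval.start, b.source_start)
            hi = min(interval.end, b.source_end)
            if lo >= hi:
                continue
            any_coverage = True
            covered += hi - lo
            if b.target_strand == "+":
                seg_lo = b.target_start + (lo - b.source_start)
                seg_hi = b.target_start + (hi - b.source_start)
            else:
                seg_lo = b.target_end - (hi - b.source_start)
                seg_hi = b.target_end - (lo - b.source_start)
            if t_chrom is None:
                t_chrom, t_min, t_max, strand = b.target_chrom, seg_lo, seg_hi, b.target_strand
            else:
                t_min = min(t_min, seg_lo)
                t_max = max(t_max, seg_hi)
        if t_chrom is None:
            continue
        if covered + 1e-9 >= min_match * len(interval):
            mapped = GenomicInterval(t_chrom, t_min, t_max, name=interval.name, strand=strand)
            candidates.append((covered, rid, mapped))
    if not any_coverage:
        return LiftoverResult([], NO_COVERAGE)
    if not candidates:
        return LiftoverResult([], BELOW_MIN_MATCH)
    if len(candidates) > 1 and not allow_multiple:
        return LiftoverResult([], MULTIPLE_HITS)
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return LiftoverResult([c[2] for c in candidates])
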