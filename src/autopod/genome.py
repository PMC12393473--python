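"""Genome sequences and per-position score tracks (FASTA / bedGraph)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = ["Genome", "ScoreTrack", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Nucleotide sequences keyed by chromosome name (alphabet ACGTN)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; minus-strand requests are
        reverse-complemented.  Out-of-bounds intervals raise."""
        seq = self.sequences.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chrom {interval.chrom!r}")
        if interval.end > len(seq):
            raise ValueError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chrom length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


class ScoreTrack:
    """Sparse per-position scores as non-overlapping scored intervals.

    Positions outside every scored interval have no score and are
    reported as ``None`` (never silently zero).
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in records:
            if start < 0 or start >= end:
                raise ValueError(f"invalid score interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(score)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            for (s0, e0, _), (s1, _, _) in zip(recs, recs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping score intervals on {chrom} at {s1}")
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            scores = np.array([r[2] for r in recs], dtype=float)
            self._data[chrom] = (starts, ends, scores)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._data.values())

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self._data):
            starts, ends, scores = self._data[chrom]
            for s, e, v in zip(starts, ends, scores):
                yield chrom, int(s), int(e), float(v)

    def scores_at(self, chrom: str, positions: Sequence[int]) -> list[float | None]:
        """Score at each position, ``None`` where the track is undefined."""
        if chrom not in self._data:
            return [None] * len(positions)
        starts, ends, scores = self._data[chrom]
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        out: list[float | None] = []
        for p, i in zip(pos, idx):
            if i >= 0 and p < ends[i]:
                out.append(float(scores[i]))
            else:
                out.append(None)
        return out

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                records.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        return cls(records)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, score in self.records():
                fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")
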