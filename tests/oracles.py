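"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's interval/chain arithmetic: they
expand everything to per-base arrays or dictionaries and recompute the
expected answers the slow way.
"""

from __future__ import annotations

import numpy as np

from autopod.chain import ChainBlock, ChainMap
from autopod.intervals import GenomicInterval, IntervalSet


def coverage_array(intervals, length: int, chrom: str = "chr1") -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


def runs_of(cov: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end) pairs."""
    out = []
    start = None
    for i, v in enumerate(cov):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(cov)))
    return out


def brute_overlap_count(a: GenomicInterval, bs) -> int:
    return sum(
        1
        for b in bs
        if b.chrom == a.chrom and max(a.start, b.start) < min(a.end, b.end)
    )


def brute_force_lift(interval, chain: ChainMap, allow_multiple: bool, min_match: float):
    """Per-base expansion of the chain; returns (intervals, reason)."""
    per_run: dict[int, list[tuple[str, int, str]]] = {}
    for b in chain.blocks:
        if b.source_chrom != interval.chrom:
            continue
        lo, hi = max(b.source_start, interval.start), min(b.source_end, interval.end)
        for p in range(lo, hi):
            per_run.setdefault(b.run_id, []).append(
                (b.target_chrom, b.map_position(p), b.target_strand)
            )
    if not per_run:
        return [], "no_coverage"
    candidates = []
    for rid, mapped in per_run.items():
        if len(mapped) + 1e-9 < min_match * len(interval):
            continue
        chroms = {c for c, _, _ in mapped}
        assert len(chroms) == 1, "mixed target chroms within one run"
        positions = [t for _, t, _ in mapped]
        candidates.append(
            (
                len(mapped),
                rid,
                GenomicInterval(
                    next(iter(chroms)),
                    min(positions),
                    max(positions) + 1,
                    name=interval.name,
                    strand=mapped[0][2],
                ),
            )
        )
    if not candidates:
        return [], "below_min_match"
    if len(candidates) > 1 and not allow_multiple:
        return [], "multiple_hits"
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return [c[2] for c in candidates], None


def random_chainmap(rng: np.random.Generator, source_len: int = 10_000, n_runs: int = 3) -> ChainMap:
    """Random colinear runs, non-overlapping on the source, with random
    strands and per-run target chromosomes."""
    blocks = []
    cursor = 0
    run_order = rng.permutation(n_runs)
    for idx, rid in enumerate(run_order):
        t_strand = "+" if rng.random() < 0.5 else "-"
        t_chrom = f"chrT{rid}"
        n_blocks = int(rng.integers(1, 4))
        segs = []
        for _ in range(n_blocks):
            cursor += int(rng.integers(1, 400))
            size = int(rng.integers(50, 500))
            if cursor + size > source_len:
                break
            segs.append((cursor, cursor + size))
            cursor += size
        if not segs:
            continue
        # colinear target layout with random gaps; on '-' runs the target
        # coordinates descend as the source ascends
        t_segs = []
        if t_strand == "+":
            t_cursor = int(rng.integers(0, 1000))
            for s, e in segs:
                t_segs.append((t_cursor, t_cursor + (e - s)))
                t_cursor += (e - s) + int(rng.integers(0, 200))
        else:
            total = sum(e - s for s, e in segs) + 200 * len(segs)
            t_hi = total + int(rng.integers(0, 1000))
            for s, e in segs:
                t_segs.append((t_hi - (e - s), t_hi))
                t_hi -= (e - s) + int(rng.integers(0, 200))
        for (s, e), (ts, te) in zip(segs, t_segs):
            blocks.append(ChainBlock("chr1", s, e, t_chrom, ts, te, t_strand, int(rid)))
    return ChainMap(blocks, name="random")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric summation
    over all tables with the observed margins."""
    from scipy.stats import hypergeom

    n1, n2 = a + b, c + d
    k = a + c
    lo, hi = max(0, k - n2), min(k, n1)
    p_obs = hypergeom.pmf(a, n1 + n2, k, n1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, n1 + n2, k, n1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, float(total))
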