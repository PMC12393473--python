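"""Per-base-pair enrichment rates and pairwise set comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import IntervalSet, flatten, overlaps_any
from .overlap import FeatureSet
from .simulate import VariantCatalog

__all__ = [
    "EnrichmentCell",
    "PairComparison",
    "per_bp_rate",
    "snp_rate",
    "compare_pair",
    "compare_pair_permutation",
]


@dataclass(frozen=True)
class EnrichmentCell:
    """Feature (or variant) count per covered base of an element set."""

    label: str
    feature_class: str
    overlap_count: int
    set_bp: int

    @property
    def rate(self) -> float | None:
        if self.set_bp == 0:
            return None
        return self.overlap_count / self.set_bp


@dataclass(frozen=True)
class PairComparison:
    label_a: str
    label_b: str
    feature_class: str
    rate_ratio: float | None
    p_value: float
    test: str


def per_bp_rate(element_set: IntervalSet, feature_set: FeatureSet) -> EnrichmentCell:
    """Number of *features* overlapping the set's covered bases, divided
    by the covered base count.  The denominator is coverage-based, so
    splitting an element into abutting fragments changes nothing."""
    flat = flatten(element_set)
    count = sum(overlaps_any(feature_set.intervals, flat))
    return EnrichmentCell(
        label=element_set.label,
        feature_class=feature_set.feature_class,
        overlap_count=count,
        set_bp=flat.covered_bp(),
    )


def snp_rate(
    element_set: IntervalSet, catalog: VariantCatalog, maf_threshold: float = 0.05
) -> EnrichmentCell:
    """Common variants (MAF strictly > threshold) falling inside the set,
    per covered base."""
    flat = flatten(element_set)
    common = catalog.common_positions(maf_threshold)
    count = sum(overlaps_any(common, flat))
    return EnrichmentCell(
        label=element_set.label,
        feature_class=f"{catalog.species}_snps",
        overlap_count=count,
        set_bp=flat.covered_bp(),
    )


def compare_pair(cell_a: EnrichmentCell, cell_b: EnrichmentCell) -> PairComparison:
    """Rate ratio plus a two-sided Fisher exact p on the bp-level 2×2
    table [(count_a, bp_a − count_a), (count_b, bp_b − count_b)].

    When ``rate_b`` is zero the ratio is undefined (None) but the p-value
    is still computed.
    """
    if cell_a.rate is None or cell_b.rate is None:
        raise ValueError("both cells must have a defined rate (set_bp > 0)")
    table = [
        [cell_a.overlap_count, cell_a.set_bp - cell_a.overlap_count],
        [cell_b.overlap_count, cell_b.set_bp - cell_b.overlap_count],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    ratio = cell_a.rate / cell_b.rate if cell_b.rate > 0 else None
    return PairComparison(
        label_a=cell_a.label,
        label_b=cell_b.label,
        feature_class=cell_a.feature_class,
        rate_ratio=ratio,
        p_value=float(p),
        test="fisher_exact",
    )


def compare_pair_permutation(
    element_set_a: IntervalSet,
    element_set_b: IntervalSet,
    feature_set: FeatureSet,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PairComparison:
    """Permutation alternative to :func:`compare_pair`.

    Each feature is reduced to its midpoint and re-placed uniformly over
    the union footprint of the two sets; the statistic is the difference
    of per-bp midpoint rates.  Two-sided p with the +1 correction.
    """
    flat_a = flatten(element_set_a)
    flat_b = flatten(element_set_b)
    bp_a, bp_b = flat_a.covered_bp(), flat_b.covered_bp()
    if bp_a == 0 or bp_b == 0:
        raise ValueError("both sets must cover ≥1 base")
    union = flatten(IntervalSet(list(flat_a) + list(flat_b)))
    positions = np.concatenate(
        [np.arange(iv.start, iv.end) for iv in union]
    )
    chrom_of = np.concatenate(
        [np.full(len(iv), i) for i, iv in enumerate(union)]
    )
    chroms = [iv.chrom for iv in union]

    def count_in(flat: IntervalSet, pos_idx: np.ndarray) -> int:
        return sum(
            1
            for i in pos_idx
            if flat.covers(chroms[chrom_of[i]], int(positions[i]))
        )

    midpoints = [(iv.chrom, iv.midpoint) for iv in feature_set.intervals]
    obs_a = sum(1 for c, p in midpoints if flat_a.covers(c, p))
    obs_b = sum(1 for c, p in midpoints if flat_b.covers(c, p))
    obs_stat = obs_a / bp_a - obs_b / bp_b

    rng = np.random.default_rng(seed)
    n_features = len(midpoints)
    hits = 0
    for _ in range(n_permutations):
        idx = rng.integers(0, len(positions), size=n_features)
        perm_a = count_in(flat_a, idx)
        perm_b = count_in(flat_b, idx)
        if abs(perm_a / bp_a - perm_b / bp_b) >= abs(obs_stat) - 1e-15:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PairComparison(
        label_a=element_set_a.label,
        label_b=element_set_b.label,
        feature_class=feature_set.feature_class,
        rate_ratio=(obs_a / bp_a) / (obs_b / bp_b) if obs_b else None,
        p_value=p,
        test="permutation",
    )
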