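"""Overlap counting between element sets and evolutionary feature sets."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalSet,
    flank_windows,
    intersect_count,
    overlaps_any,
)

__all__ = [
    "FeatureSet",
    "count_overlapping_elements",
    "count_features_hit",
    "overlap_report",
    "flanking_feature_report",
    "gene_proximity_counts",
    "correlate_set_counts",
    "expected_differential_count",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("HAR", "hCONDEL", "HAQER", "inversion", "SDR", "custom")


@dataclass(frozen=True)
class FeatureSet:
    """A labeled class of evolutionary feature intervals."""

    feature_class: str
    intervals: IntervalSet

    def __post_init__(self) -> None:
        if not self.feature_class:
            raise ValueError("feature_class must be set")


def count_overlapping_elements(element_set: IntervalSet, feature_set: FeatureSet) -> int:
    """Elements overlapping ≥1 feature by ≥1 bp; each element counts once
    no matter how many features it hits."""
    return sum(overlaps_any(element_set, feature_set.intervals))


def count_features_hit(element_set: IntervalSet, feature_set: FeatureSet) -> int:
    """Distinct feature intervals overlapping ≥1 element."""
    return sum(overlaps_any(feature_set.intervals, element_set))


def overlap_report(
    element_sets: Mapping[str, IntervalSet], feature_sets: Sequence[FeatureSet]
) -> pd.DataFrame:
    """Both tallies per (element set, feature class): elements overlapping
    features and distinct features hit."""
    rows = []
    for label, elems in element_sets.items():
        for fs in feature_sets:
            rows.append(
                {
                    "element_set": label,
                    "feature_class": fs.feature_class,
                    "n_elements_overlapping": count_overlapping_elements(elems, fs),
                    "n_features_hit": count_features_hit(elems, fs),
                    "n_elements_total": len(elems),
                }
            )
    return pd.DataFrame(rows)


def flanking_feature_report(
    element_set: IntervalSet,
    feature_set: FeatureSet,
    chrom_lengths: Mapping[str, int],
    widths: Sequence[int] = (500_000, 1_000_000),
) -> dict[int, int]:
    """Elements overlapping the flank windows of each feature (bodies
    excluded), per window width."""
    out: dict[int, int] = {}
    for width in widths:
        flanks = flank_windows(feature_set.intervals, width, chrom_lengths)
        out[width] = sum(overlaps_any(element_set, flanks))
    return out


def gene_proximity_counts(
    gene_spans: IntervalSet,
    element_sets: Mapping[str, IntervalSet],
    expression_table: Mapping[str, float],
    window: int = 500_000,
    min_expression: float = 10.0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per passing gene, the number of elements of each set within
    ``window`` bp of the gene span.

    Genes are kept when their maximum normalized expression is
    ``≥ min_expression`` (inclusive); genes absent from the expression
    table are excluded with a logged warning.
    """
    kept: list[GenomicInterval] = []
    for iv in gene_spans:
        gene = iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        if gene not in expression_table:
            logger.warning("gene %s missing from expression table; excluded", gene)
            continue
        if expression_table[gene] < min_expression:
            continue
        clen = chrom_lengths.get(iv.chrom) if chrom_lengths else None
        start = max(0, iv.start - window)
        end = iv.end + window if clen is None else min(clen, iv.end + window)
        kept.append(GenomicInterval(iv.chrom, start, end, name=gene))
    extended = IntervalSet(kept, label="extended_genes")
    data = {
        label: intersect_count(extended, elems)
        for label, elems in element_sets.items()
    }
    return pd.DataFrame(data, index=[iv.name for iv in extended])


def correlate_set_counts(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Pearson correlation of paired per-gene counts.

    Zero variance in either vector makes the statistic undefined and is
    reported as ``(nan, nan)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired count vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need n ≥ 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(a, b)
    return (float(r), float(p))


def expected_differential_count(n_overlaps: int, empirical_rate: float) -> int:
    """``round(n_overlaps × rate)`` to the nearest integer, halves away
    from zero."""
    if n_overlaps < 0:
        raise ValueError("n_overlaps must be ≥ 0")
    if not (0.0 <= empirical_rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    return int(math.floor(n_overlaps * empirical_rate + 0.5))
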