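"""Accessibility-pattern classification and anatomical partitioning.

The atlas is an element × condition boolean matrix on a unified element
universe: a condition is a (limb, digit, region, timepoint) combination,
a "tissue" collapses the timepoint (an element restricted to one tissue
at one or both timepoints is tissue-and-timepoint specific).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlaps_any, read_bed, write_bed

__all__ = [
    "ConditionLabel",
    "AccessibilityAtlas",
    "PartitionResult",
    "CrossSpeciesSharing",
    "autopod_conditions",
    "brain_filter",
    "classify_specificity",
    "partition_by_axis",
    "sharing_profile",
    "cross_species_shared",
]

LIMBS = ("hand", "foot")
DIGITS = ("I", "II", "III", "IV", "V")
REGIONS = ("phalanges", "metapodial")
TIMEPOINTS = ("early", "late")

_AXES = {
    "limb": ("limb", LIMBS),
    "region": ("region", REGIONS),
    "timepoint": ("timepoint", TIMEPOINTS),
}


@dataclass(frozen=True)
class ConditionLabel:
    """One assayed condition: limb × digit × region × timepoint."""

    limb: str
    digit: str
    region: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}")
        if self.digit not in DIGITS:
            raise ValueError(f"unknown digit {self.digit!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    @property
    def tissue(self) -> tuple[str, str, str]:
        """Tissue identity ignoring timepoint."""
        return (self.limb, self.digit, self.region)

    def __str__(self) -> str:
        return f"{self.limb}.{self.digit}.{self.region}.{self.timepoint}"

    @classmethod
    def parse(cls, text: str) -> "ConditionLabel":
        parts = text.split(".")
        if len(parts) != 4:
            raise ValueError(f"cannot parse condition label {text!r}")
        return cls(*parts)


def autopod_conditions() -> tuple[ConditionLabel, ...]:
    """All 2 limbs × 5 digits × 2 regions × 2 timepoints = 40 conditions."""
    return tuple(
        ConditionLabel(l, d, r, t)
        for l in LIMBS
        for d in DIGITS
        for r in REGIONS
        for t in TIMEPOINTS
    )


class AccessibilityAtlas:
    """Elements plus a boolean accessibility matrix over conditions."""

    def __init__(
        self,
        elements: IntervalSet,
        conditions: Sequence[ConditionLabel],
        matrix: np.ndarray,
    ):
        matrix = np.asarray(matrix, dtype=bool)
        if matrix.shape != (len(elements), len(conditions)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(elements)} elements × {len(conditions)} conditions"
            )
        if len(elements) and not matrix.any(axis=1).all():
            raise ValueError("every element must be accessible in ≥1 condition")
        self.elements = elements
        self.conditions = tuple(conditions)
        self.matrix = matrix

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_names(self) -> list[str]:
        return [
            iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.elements
        ]

    def subset(self, mask: Sequence[bool]) -> "AccessibilityAtlas":
        mask = np.asarray(mask, dtype=bool)
        kept = [iv for iv, m in zip(self.elements, mask) if m]
        return AccessibilityAtlas(
            IntervalSet(kept, label=self.elements.label),
            self.conditions,
            self.matrix[mask],
        )

    def condition_mask(self, **fields: str) -> np.ndarray:
        """Boolean mask over conditions matching the given field values."""
        return np.array(
            [
                all(getattr(c, k) == v for k, v in fields.items())
                for c in self.conditions
            ]
        )

    # ----------------------------------------------------------- persistence

    def to_files(self, bed_path, matrix_path) -> None:
        write_bed(self.elements, bed_path)
        df = pd.DataFrame(
            self.matrix.astype(int),
            index=self.element_names,
            columns=[str(c) for c in self.conditions],
        )
        df.index.name = "element"
        df.to_csv(matrix_path, sep="\t")

    @classmethod
    def from_files(cls, bed_path, matrix_path) -> "AccessibilityAtlas":
        elements = read_bed(bed_path, label="elements")
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        conditions = tuple(ConditionLabel.parse(c) for c in df.columns)
        names = [
            iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in elements
        ]
        matrix = df.loc[names].to_numpy(dtype=bool)
        return cls(elements, conditions, matrix)


@dataclass
class PartitionResult:
    """Disjoint three-way split of an element set along one axis."""

    axis: str
    a_label: str
    b_label: str
    a_only: IntervalSet
    b_only: IntervalSet
    shared: IntervalSet

    def subsets(self) -> dict[str, IntervalSet]:
        return {
            f"{self.a_label}_only": self.a_only,
            f"{self.b_label}_only": self.b_only,
            "shared": self.shared,
        }


@dataclass
class CrossSpeciesSharing:
    n_shared: int
    n_total: int
    fraction: float
    n_shared_autopod_specific: int | None = None
    n_autopod_specific: int | None = None
    fraction_autopod_specific: float | None = None


def brain_filter(atlas: AccessibilityAtlas, brain_set: IntervalSet) -> AccessibilityAtlas:
    """Drop every element overlapping a brain peak by ≥1 bp (whole-element
    removal, mirroring peak-level housekeeping filtering)."""
    hits = overlaps_any(atlas.elements, brain_set)
    return atlas.subset([not h for h in hits])


def classify_specificity(
    atlas: AccessibilityAtlas, other_skeleton_sets: Sequence[IntervalSet]
) -> pd.DataFrame:
    """Per-element categories, reported independently.

    ``autopod_specific``: no overlap with any other-skeleton element set.
    ``tissue_and_timepoint_specific``: accessible in exactly one tissue
    (limb, digit, region), at one or both timepoints.
    ``shared_with_skeleton``: complement of autopod_specific.
    """
    shared = np.zeros(atlas.n_elements, dtype=bool)
    for s in other_skeleton_sets:
        shared |= np.array(overlaps_any(atlas.elements, s))
    tissues = [c.tissue for c in atlas.conditions]
    tissue_specific = np.array(
        [
            len({t for t, on in zip(tissues, row) if on}) == 1
            for row in atlas.matrix
        ]
    )
    return pd.DataFrame(
        {
            "autopod_specific": ~shared,
            "shared_with_skeleton": shared,
            "tissue_and_timepoint_specific": tissue_specific,
        },
        index=atlas.element_names,
    )


def partition_by_axis(
    atlas: AccessibilityAtlas, axis: str, restricted: bool = True
) -> PartitionResult:
    """Split elements into A-only / B-only / shared along ``axis``
    (limb: hand/foot, region: phalanges/metapodial, timepoint: early/late).

    The caller is expected to pass an autopod-specific subset; set
    ``restricted=False`` to acknowledge an unrestricted input.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(_AXES)}")
    if not restricted:
        pass  # caller explicitly opted out of the autopod-specific restriction
    field_name, (a_val, b_val) = _AXES[axis]
    a_mask = atlas.condition_mask(**{field_name: a_val})
    b_mask = atlas.condition_mask(**{field_name: b_val})
    in_a = atlas.matrix[:, a_mask].any(axis=1)
    in_b = atlas.matrix[:, b_mask].any(axis=1)

    def pick(mask: np.ndarray, label: str) -> IntervalSet:
        return IntervalSet(
            [iv for iv, m in zip(atlas.elements, mask) if m], label=label
        )

    result = PartitionResult(
        axis=axis,
        a_label=a_val,
        b_label=b_val,
        a_only=pick(in_a & ~in_b, f"{a_val}_only"),
        b_only=pick(in_b & ~in_a, f"{b_val}_only"),
        shared=pick(in_a & in_b, "shared"),
    )
    total = len(result.a_only) + len(result.b_only) + len(result.shared)
    if total != atlas.n_elements:
        raise AssertionError("partition subsets do not cover the input")
    return result


def sharing_profile(
    atlas: AccessibilityAtlas, min_combination_size: int = 5
) -> dict[tuple[int, int], int]:
    """Tally elements by (number of early, number of late) accessible
    conditions, after dropping condition combinations carried by fewer
    than ``min_combination_size`` elements."""
    if min_combination_size < 1:
        raise ValueError("min_combination_size must be ≥ 1")
    early = np.array([c.timepoint == "early" for c in atlas.conditions])
    combos: dict[bytes, int] = {}
    for row in atlas.matrix:
        combos[row.tobytes()] = combos.get(row.tobytes(), 0) + 1
    profile: dict[tuple[int, int], int] = {}
    for key, count in combos.items():
        if count < min_combination_size:
            continue
        row = np.frombuffer(key, dtype=bool)
        cell = (int(row[early].sum()), int(row[~early].sum()))
        profile[cell] = profile.get(cell, 0) + count
    return profile


def cross_species_shared(
    atlas: AccessibilityAtlas,
    lifted_other_species_set: IntervalSet,
    autopod_specific: Sequence[bool] | None = None,
) -> CrossSpeciesSharing:
    """Elements overlapping ≥1 lifted other-species element, as a count
    and a fraction of the atlas; optionally also restricted to an
    autopod-specific mask."""
    hits = np.array(overlaps_any(atlas.elements, lifted_other_species_set))
    n_total = atlas.n_elements
    n_shared = int(hits.sum())
    result = CrossSpeciesSharing(
        n_shared=n_shared,
        n_total=n_total,
        fraction=n_shared / n_total if n_total else float("nan"),
    )
    if autopod_specific is not None:
        mask = np.asarray(autopod_specific, dtype=bool)
        n_ap = int(mask.sum())
        n_ap_shared = int((hits & mask).sum())
        result.n_shared_autopod_specific = n_ap_shared
        result.n_autopod_specific = n_ap
        result.fraction_autopod_specific = n_ap_shared / n_ap if n_ap else float("nan")
    return result
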