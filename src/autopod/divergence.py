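"""Lineage-specific fixed-substitution survey in a three-genome context.

The pipeline standardizes each element to a fixed length, masks common
polymorphisms and blacklisted bases, requires full-length single-locus
mappability to both non-target genomes, gates fragments on sequence
identity, and calls a base derived on a lineage when that genome differs
while the other two agree.  Conservation-score shifts between the two
lineages' derived positions are compared with a two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .chain import ChainMap, liftover_interval
from .genome import Genome, ScoreTrack
from .intervals import GenomicInterval, IntervalSet, subtract
from .simulate import VariantCatalog

__all__ = [
    "DivergenceConfig",
    "TrioContext",
    "SurveyedFragment",
    "DivergenceReport",
    "ShiftTestResult",
    "standardize_to_length",
    "mask_and_fragment",
    "map_fragment_to_trio",
    "sequence_identity",
    "call_derived_positions",
    "run_divergence",
    "conservation_shift_test",
]

TARGET = "target"
SISTER = "sister"


@dataclass(frozen=True)
class DivergenceConfig:
    """Tunables of the survey.

    ``identity_rule`` controls how the two identity gates combine:
    ``"and"`` (default, conservative) requires the focal genome to reach
    ``min_identity`` against *both* other genomes; ``"or"`` against
    either.
    """

    standard_length: int = 500
    maf_threshold: float = 0.05
    min_identity: float = 0.25
    identity_rule: str = "and"

    def __post_init__(self) -> None:
        if self.standard_length < 1:
            raise ValueError("standard_length must be ≥ 1")
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in (0, 1]")
        if self.identity_rule not in ("and", "or"):
            raise ValueError("identity_rule must be 'and' or 'or'")


@dataclass
class TrioContext:
    """All inputs of the survey: three genomes, the two chains from the
    target, per-species variant catalogs, the blacklist, and (optionally)
    a conservation score track on target coordinates."""

    target: Genome
    sister: Genome
    outgroup: Genome
    chain_to_sister: ChainMap
    chain_to_outgroup: ChainMap
    catalogs: Mapping[str, VariantCatalog]
    blacklist: IntervalSet
    score_track: ScoreTrack | None = None


@dataclass
class SurveyedFragment:
    """One fragment with its aligned sister/outgroup sequences, pairwise
    identities, or a rejection reason when unmappable."""

    interval: GenomicInterval
    target_seq: str | None = None
    sister_seq: str | None = None
    outgroup_seq: str | None = None
    identity_to_sister: float | None = None
    identity_to_outgroup: float | None = None
    identity_sister_outgroup: float | None = None
    rejection_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejection_reason is None


@dataclass
class DivergenceReport:
    """Per element set and lineage: surveyed bases, derived calls, and
    conservation scores at the derived positions."""

    set_label: str
    lineage: str
    bp_surveyed: int = 0
    derived_count: int = 0
    derived_positions: list[tuple[str, int]] = field(default_factory=list)
    scores: list[float | None] = field(default_factory=list)
    rejections: Counter = field(default_factory=Counter)

    @property
    def rate_per_bp(self) -> float | None:
        if self.bp_surveyed == 0:
            return None
        return self.derived_count / self.bp_surveyed


@dataclass
class ShiftTestResult:
    mean_a: float
    mean_b: float
    p_value: float
    n_a: int
    n_b: int
    n_missing: int


def standardize_to_length(
    interval: GenomicInterval, length: int, chrom_lengths: Mapping[str, int]
) -> GenomicInterval | None:
    """Recenter ``interval`` on its midpoint at exactly ``length`` bp.

    Returns ``None`` when the window would extend past the chromosome
    bounds — such elements are rejected rather than clamped, so every
    surviving element has identical length.
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    mid = interval.midpoint
    start = mid - length // 2
    end = start + length
    clen = chrom_lengths.get(interval.chrom)
    if clen is None:
        raise KeyError(f"unknown chrom length for {interval.chrom!r}")
    if start < 0 or end > clen:
        return None
    return GenomicInterval(interval.chrom, start, end, name=interval.name, strand=interval.strand)


def mask_and_fragment(
    intervals: IntervalSet,
    catalogs: Mapping[str, VariantCatalog],
    maf_threshold: float = 0.05,
    blacklist: IntervalSet | None = None,
) -> IntervalSet:
    """Subtract common-variant positions (MAF strictly above threshold in
    *any* species) and blacklist bases; elements may split into several
    fragments, each keeping its parent element's name."""
    mask: list[GenomicInterval] = []
    for cat in catalogs.values():
        mask.extend(cat.common_positions(maf_threshold))
    if blacklist is not None:
        mask.extend(blacklist)
    return subtract(intervals, IntervalSet(mask))


def map_fragment_to_trio(fragment: GenomicInterval, context: TrioContext) -> SurveyedFragment:
    """Lift ``fragment`` to sister and outgroup requiring full-length,
    single-locus mappability; fetch the three sequences (strand-aware)
    and compute pairwise identities."""
    seqs: dict[str, str] = {}
    for label, chain, genome in (
        ("sister", context.chain_to_sister, context.sister),
        ("outgroup", context.chain_to_outgroup, context.outgroup),
    ):
        result = liftover_interval(fragment, chain, allow_multiple=False, min_match=1.0)
        if not result:
            return SurveyedFragment(
                fragment, rejection_reason=f"unmappable_{label}:{result.reason}"
            )
        mapped = result.intervals[0]
        if len(mapped) != len(fragment):
            return SurveyedFragment(
                fragment, rejection_reason=f"unmappable_{label}:gapped_target"
            )
        seqs[label] = genome.fetch(mapped)
    target_seq = context.target.fetch(fragment)
    return SurveyedFragment(
        fragment,
        target_seq=target_seq,
        sister_seq=seqs["sister"],
        outgroup_seq=seqs["outgroup"],
        identity_to_sister=sequence_identity(target_seq, seqs["sister"]),
        identity_to_outgroup=sequence_identity(target_seq, seqs["outgroup"]),
        identity_sister_outgroup=sequence_identity(seqs["sister"], seqs["outgroup"]),
    )


def sequence_identity(a: str, b: str) -> float:
    """Fraction of positions with identical nucleotides; positions where
    either base is N are excluded from both numerator and denominator.
    All-N comparisons return nan."""
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("empty sequences")
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        return float("nan")
    return matches / comparable


def call_derived_positions(surveyed: SurveyedFragment, lineage: str = TARGET) -> list[int]:
    """Absolute target-genome positions derived on ``lineage``: the focal
    genome differs while the other two genomes agree, no base being N."""
    if not surveyed.accepted:
        raise ValueError("cannot call derived positions on a rejected fragment")
    t, s, o = surveyed.target_seq, surveyed.sister_seq, surveyed.outgroup_seq
    start = surveyed.interval.start
    out = []
    for i, (x, y, z) in enumerate(zip(t, s, o)):
        if "N" in (x, y, z):
            continue
        if lineage == TARGET:
            if x != y and y == z:
                out.append(start + i)
        elif lineage == SISTER:
            if y != x and x == z:
                out.append(start + i)
        else:
            raise ValueError(f"unknown lineage {lineage!r}")
    return out


def _passes_gate(surveyed: SurveyedFragment, lineage: str, config: DivergenceConfig) -> bool:
    if lineage == TARGET:
        ids = (surveyed.identity_to_sister, surveyed.identity_to_outgroup)
    else:
        ids = (surveyed.identity_to_sister, surveyed.identity_sister_outgroup)
    checks = [
        (v is not None and not np.isnan(v) and v >= config.min_identity) for v in ids
    ]
    return all(checks) if config.identity_rule == "and" else any(checks)


def _comparable_bp(surveyed: SurveyedFragment) -> int:
    return sum(
        1
        for x, y, z in zip(
            surveyed.target_seq, surveyed.sister_seq, surveyed.outgroup_seq
        )
        if "N" not in (x, y, z)
    )


def run_divergence(
    element_sets: Mapping[str, IntervalSet],
    context: TrioContext,
    config: DivergenceConfig = DivergenceConfig(),
) -> dict[str, dict[str, DivergenceReport]]:
    """Full survey of each element set, for both lineages.

    Pipeline order: standardize → mask/fragment → map to trio → identity
    gate → derived calls → aggregate.  Both lineages are read off the
    same surveyed fragments — swapping the focal lineage only changes
    which genome's mismatches are counted (and which identity gates
    apply), never the underlying alignment.
    """
    chrom_lengths = context.target.lengths
    reports: dict[str, dict[str, DivergenceReport]] = {}
    for label, elements in element_sets.items():
        per_lineage = {
            lineage: DivergenceReport(set_label=label, lineage=lineage)
            for lineage in (TARGET, SISTER)
        }
        standardized: list[GenomicInterval] = []
        for iv in elements:
            std = standardize_to_length(iv, config.standard_length, chrom_lengths)
            if std is None:
                for rep in per_lineage.values():
                    rep.rejections["standardization_out_of_bounds"] += 1
            else:
                standardized.append(std)
        fragments = mask_and_fragment(
            IntervalSet(standardized, label=label),
            context.catalogs,
            config.maf_threshold,
            context.blacklist,
        )
        for fragment in fragments:
            surveyed = map_fragment_to_trio(fragment, context)
            if not surveyed.accepted:
                for rep in per_lineage.values():
                    rep.rejections[surveyed.rejection_reason] += 1
                continue
            for lineage, rep in per_lineage.items():
                if not _passes_gate(surveyed, lineage, config):
                    rep.rejections["below_min_identity"] += 1
                    continue
                rep.bp_surveyed += _comparable_bp(surveyed)
                positions = call_derived_positions(surveyed, lineage)
                rep.derived_count += len(positions)
                rep.derived_positions.extend(
                    (fragment.chrom, p) for p in positions
                )
        if context.score_track is not None:
            for rep in per_lineage.values():
                by_chrom: dict[str, list[int]] = {}
                for chrom, p in rep.derived_positions:
                    by_chrom.setdefault(chrom, []).append(p)
                scores: list[float | None] = []
                for chrom, pos in by_chrom.items():
                    scores.extend(context.score_track.scores_at(chrom, pos))
                rep.scores = scores
        reports[label] = per_lineage
    return reports


def conservation_shift_test(
    scores_target_derived: Sequence[float | None],
    scores_sister_derived: Sequence[float | None],
) -> ShiftTestResult:
    """Two-sided Wilcoxon rank-sum comparison of conservation scores at
    the two lineages' derived positions.  Missing scores (None/nan) are
    excluded and their count reported."""
    def clean(values: Sequence[float | None]) -> list[float]:
        return [float(v) for v in values if v is not None and not np.isnan(v)]

    a = clean(scores_target_derived)
    b = clean(scores_sister_derived)
    n_missing = (len(scores_target_derived) - len(a)) + (len(scores_sister_derived) - len(b))
    if not a or not b:
        raise ValueError("both score lists must be non-empty after removing missing values")
    stat = stats.ranksums(a, b)
    return ShiftTestResult(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        p_value=float(stat.pvalue),
        n_a=len(a),
        n_b=len(b),
        n_missing=n_missing,
    )
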