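"""Synthetic inputs with planted truth.

Everything the pipeline consumes can be generated here: a trio of
near-identical genomes with known lineage-specific substitutions,
polymorphic sites, and deletion-induced chain gaps; an element × condition
accessibility atlas with a controllable sharing structure; random feature
interval sets; a score track with a planted mean shift; and a skeletal
measurement table.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .atlas import AccessibilityAtlas, ConditionLabel
from .chain import ChainBlock, ChainMap
from .genome import Genome, ScoreTrack
from .intervals import GenomicInterval, IntervalSet, flatten

__all__ = [
    "TrioSimulationParams",
    "TruthTable",
    "VariantCatalog",
    "TrioData",
    "simulate_trio",
    "simulate_atlas",
    "simulate_score_track",
    "random_intervals",
    "simulate_measurements",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantCatalog:
    """Single-nucleotide polymorphisms of one species with minor-allele
    frequencies, expressed in *target-genome* coordinates (pre-lifted)."""

    species: str
    records: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for chrom, pos, maf in self.records:
            if not (0.0 <= maf <= 0.5):
                raise ValueError(f"MAF {maf} out of [0, 0.5] at {chrom}:{pos}")
            if (chrom, pos) in seen:
                raise ValueError(f"duplicate position {chrom}:{pos}")
            seen.add((chrom, pos))

    def common_positions(self, maf_threshold: float = 0.05) -> IntervalSet:
        """1-bp intervals at positions with MAF strictly above threshold."""
        return IntervalSet(
            [
                GenomicInterval(chrom, pos, pos + 1)
                for chrom, pos, maf in self.records
                if maf > maf_threshold
            ],
            label=f"{self.species}_common_snps",
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tmaf\n")
            for chrom, pos, maf in self.records:
                fh.write(f"{chrom}\t{pos}\t{maf:.6f}\n")

    @classmethod
    def from_tsv(cls, path, species: str) -> "VariantCatalog":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chrom, pos, maf = line.split("\t")
                records.append((chrom, int(pos), float(maf)))
        return cls(species, tuple(records))


@dataclass
class TrioSimulationParams:
    """Knobs for :func:`simulate_trio`.

    ``indel_blocks`` are ``(position, length)`` deletions applied to both
    the sister and the outgroup genome; the deleted span is absent from
    the chains and therefore unmappable from the target.
    """

    chrom_length: int
    n_target_fixed: int = 0
    n_sister_fixed: int = 0
    n_shared_polymorphic: int = 0
    indel_blocks: Sequence[tuple[int, int]] = field(default_factory=tuple)
    blacklist_regions: Sequence[tuple[int, int]] = field(default_factory=tuple)
    chrom: str = "chr1"
    seed: int = 0
    species: tuple[str, str, str] = ("target", "sister", "outgroup")

    def __post_init__(self) -> None:
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be ≥ 1")
        for pos, length in self.indel_blocks:
            if pos < 0 or length < 1 or pos + length > self.chrom_length:
                raise ValueError(f"indel block ({pos}, {length}) out of range")
        spans = sorted((p, p + l) for p, l in self.indel_blocks)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("indel blocks overlap")


@dataclass
class TruthTable:
    """Ground truth of a trio simulation, in target coordinates."""

    target_fixed: tuple[int, ...]
    sister_fixed: tuple[int, ...]
    polymorphic: dict[str, tuple[tuple[int, float], ...]]
    unmappable_blocks: tuple[tuple[int, int], ...]


@dataclass
class TrioData:
    target: Genome
    sister: Genome
    outgroup: Genome
    chain_to_sister: ChainMap
    chain_to_outgroup: ChainMap
    catalogs: dict[str, VariantCatalog]
    blacklist: IntervalSet
    truth: TruthTable

    def write(self, outdir, chain_dialect: str = "tsv") -> None:
        """Write all artifacts as plain-text files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.target.to_fasta(outdir / "target.fa")
        self.sister.to_fasta(outdir / "sister.fa")
        self.outgroup.to_fasta(outdir / "outgroup.fa")
        for label, chain, other in (
            ("sister", self.chain_to_sister, self.sister),
            ("outgroup", self.chain_to_outgroup, self.outgroup),
        ):
            chain.to_tsv(outdir / f"target_to_{label}.chain.tsv")
            if chain_dialect in ("ucsc", "both"):
                chain.to_ucsc(
                    outdir / f"target_to_{label}.chain",
                    self.target.lengths,
                    other.lengths,
                )
        for species, cat in self.catalogs.items():
            cat.to_tsv(outdir / f"{species}.variants.tsv")
        from .intervals import write_bed

        write_bed(self.blacklist, outdir / "blacklist.bed")


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [n for n in "ACGT" if n != base]
    return choices[rng.integers(0, 3)]


def _deletion_chain(
    chrom: str, length: int, deletions: Sequence[tuple[int, int]], name: str
) -> ChainMap:
    """Chain from the full-length target to a genome with blocks deleted."""
    blocks: list[ChainBlock] = []
    cursor = 0
    shifted = 0
    for pos, dlen in sorted(deletions):
        if pos > cursor:
            blocks.append(
                ChainBlock(chrom, cursor, pos, chrom, shifted, shifted + (pos - cursor), "+", 1)
            )
            shifted += pos - cursor
        cursor = pos + dlen
    if cursor < length:
        blocks.append(
            ChainBlock(chrom, cursor, length, chrom, shifted, shifted + (length - cursor), "+", 1)
        )
    return ChainMap(blocks, name=name)


def simulate_trio(params: TrioSimulationParams) -> TrioData:
    """Generate a target/sister/outgroup trio with planted substitutions.

    The ancestor is drawn uniformly over ACGT.  Target-lineage
    substitutions change the target base while sister and outgroup keep
    the ancestral state (and symmetrically for the sister lineage); fixed
    positions are distinct across lineages and placed outside indel
    blocks so every planted change is recoverable by parsimony.
    Polymorphic sites may coincide with fixed positions — masking is
    expected to resolve those.
    """
    rng = np.random.default_rng(params.seed)
    L = params.chrom_length
    chrom = params.chrom
    ancestor = rng.choice(_NUCS, size=L)

    deleted = np.zeros(L, dtype=bool)
    for pos, dlen in params.indel_blocks:
        deleted[pos : pos + dlen] = True
    candidates = np.flatnonzero(~deleted)
    n_fixed = params.n_target_fixed + params.n_sister_fixed
    if n_fixed > len(candidates):
        raise ValueError(
            f"cannot place {n_fixed} fixed substitutions on "
            f"{len(candidates)} available positions"
        )
    fixed_pos = rng.choice(candidates, size=n_fixed, replace=False)
    target_pos = np.sort(fixed_pos[: params.n_target_fixed])
    sister_pos = np.sort(fixed_pos[params.n_target_fixed :])

    target_seq = ancestor.copy()
    sister_full = ancestor.copy()
    for p in target_pos:
        target_seq[p] = _mutate(str(ancestor[p]), rng)
    for p in sister_pos:
        sister_full[p] = _mutate(str(ancestor[p]), rng)

    keep = ~deleted
    target = Genome({chrom: "".join(target_seq)})
    sister = Genome({chrom: "".join(sister_full[keep])})
    outgroup = Genome({chrom: "".join(ancestor[keep])})

    chain_sister = _deletion_chain(chrom, L, params.indel_blocks, "target_to_sister")
    chain_outgroup = _deletion_chain(chrom, L, params.indel_blocks, "target_to_outgroup")

    polymorphic: dict[str, tuple[tuple[int, float], ...]] = {}
    catalogs: dict[str, VariantCatalog] = {}
    for species in params.species:
        if params.n_shared_polymorphic > L:
            raise ValueError("more polymorphic sites than positions")
        pos = np.sort(rng.choice(L, size=params.n_shared_polymorphic, replace=False))
        maf = rng.uniform(0.001, 0.5, size=params.n_shared_polymorphic)
        recs = tuple((int(p), float(round(f, 6))) for p, f in zip(pos, maf))
        polymorphic[species] = recs
        catalogs[species] = VariantCatalog(
            species, tuple((chrom, p, f) for p, f in recs)
        )

    blacklist = IntervalSet(
        [GenomicInterval(chrom, s, e) for s, e in params.blacklist_regions],
        label="blacklist",
    )
    truth = TruthTable(
        target_fixed=tuple(int(p) for p in target_pos),
        sister_fixed=tuple(int(p) for p in sister_pos),
        polymorphic=polymorphic,
        unmappable_blocks=tuple((int(p), int(p + l)) for p, l in sorted(params.indel_blocks)),
    )
    return TrioData(
        target, sister, outgroup, chain_sister, chain_outgroup,
        catalogs, blacklist, truth,
    )


def simulate_atlas(
    n_elements: int,
    conditions: Sequence[ConditionLabel],
    sharing_spec: Sequence[tuple[Sequence[ConditionLabel], float]],
    seed: int = 0,
    element_length: int = 500,
    spacing: int = 1000,
    chrom: str = "chr1",
    chrom_length: int | None = None,
) -> tuple[IntervalSet, AccessibilityAtlas]:
    """Non-overlapping elements plus an accessibility matrix drawn from a
    mixture of condition combinations.

    ``sharing_spec`` lists ``(combination, probability)`` pairs; each
    element is assigned one combination.  Probabilities must sum to 1
    and every combination must contain ≥1 condition.
    """
    if spacing < element_length:
        raise ValueError("spacing must be ≥ element_length")
    if chrom_length is not None and n_elements * spacing > chrom_length:
        raise ValueError(
            f"{n_elements} elements at spacing {spacing} exceed chrom length {chrom_length}"
        )
    probs = np.array([p for _, p in sharing_spec], dtype=float)
    if len(probs) == 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("sharing_spec probabilities must sum to 1")
    cond_index = {c: i for i, c in enumerate(conditions)}
    combos = []
    for combo, _ in sharing_spec:
        if not combo:
            raise ValueError("empty condition combination")
        combos.append([cond_index[c] for c in combo])

    rng = np.random.default_rng(seed)
    choice = rng.choice(len(combos), size=n_elements, p=probs)
    matrix = np.zeros((n_elements, len(conditions)), dtype=bool)
    for i, k in enumerate(choice):
        matrix[i, combos[k]] = True
    elements = IntervalSet(
        [
            GenomicInterval(chrom, i * spacing, i * spacing + element_length, name=f"elem_{i:05d}")
            for i in range(n_elements)
        ],
        label="elements",
    )
    return elements, AccessibilityAtlas(elements, tuple(conditions), matrix)


def simulate_score_track(
    constrained_positions: Sequence[int],
    shift: float,
    noise_sd: float,
    seed: int = 0,
    background_positions: Sequence[int] = (),
    chrom: str = "chr1",
) -> ScoreTrack:
    """Per-position scores: background ~ N(0, sd), constrained positions
    ~ N(shift, sd).  Constrained assignments win on collision."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    scores: dict[int, float] = {}
    bg = rng.normal(0.0, noise_sd, size=len(background_positions))
    for p, v in zip(background_positions, bg):
        scores[int(p)] = float(v)
    fg = rng.normal(shift, noise_sd, size=len(constrained_positions))
    for p, v in zip(constrained_positions, fg):
        scores[int(p)] = float(v)
    return ScoreTrack((chrom, p, p + 1, v) for p, v in sorted(scores.items()))


def random_intervals(
    n: int,
    chrom_length: int,
    length: int,
    seed: int = 0,
    chrom: str = "chr1",
    label: str = "features",
) -> IntervalSet:
    """``n`` random fixed-length intervals (may overlap each other)."""
    if length > chrom_length:
        raise ValueError("interval length exceeds chrom length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, chrom_length - length + 1, size=n)
    return IntervalSet(
        [GenomicInterval(chrom, int(s), int(s) + length, name=f"{label}_{i}") for i, s in enumerate(starts)],
        label=label,
    )


def simulate_measurements(
    seed: int = 0,
    n_individuals: int = 10,
    species_scale: Mapping[str, float] | None = None,
):
    """Skeletal measurement table for the anatomy stage.

    Species means differ by ``species_scale`` factors; individual values
    get multiplicative log-normal noise.  Returns a pandas DataFrame with
    the canonical measurement columns.
    """
    import pandas as pd

    from .anatomy import DIGITS, DIMENSIONS, ELEMENTS, LIMBS

    if species_scale is None:
        species_scale = {"human": 1.0, "chimpanzee": 1.25, "gorilla": 1.4}
    rng = np.random.default_rng(seed)
    rows = []
    for species, scale in species_scale.items():
        for limb in LIMBS:
            for digit in DIGITS:
                for element in ELEMENTS:
                    if element == "middle_phalanx" and digit == "I":
                        continue  # digit I has no middle phalanx
                    for dim in DIMENSIONS:
                        base = 40.0 if dim == "length" else 10.0
                        for ind in range(n_individuals):
                            noise = float(np.exp(rng.normal(0.0, 0.05)))
                            rows.append(
                                {
                                    "species": species,
                                    "individual": f"{species}_{ind}",
                                    "limb": limb,
                                    "digit": digit,
                                    "element": element,
                                    "dimension": dim,
                                    "value": round(base * scale * noise, 3),
                                }
                            )
    return pd.DataFrame(rows)
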