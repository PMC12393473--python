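"""End-to-end orchestration of the synthetic pipeline.

A single YAML config drives every stage; all outputs are TSV/CSV with a
provenance header (tool version, seed, config hash) so identical
config+seed pairs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import combine_phalanges, percent_change
from .atlas import (
    AccessibilityAtlas,
    autopod_conditions,
    brain_filter,
    classify_specificity,
    partition_by_axis,
    sharing_profile,
)
from .checks import worked_examples
from .divergence import (
    DivergenceConfig,
    TrioContext,
    conservation_shift_test,
    run_divergence,
)
from .enrichment import compare_pair, per_bp_rate, snp_rate
from .intervals import IntervalSet, write_bed
from .overlap import FeatureSet, flanking_feature_report, overlap_report
from .simulate import (
    TrioSimulationParams,
    simulate_atlas,
    simulate_measurements,
    simulate_score_track,
    simulate_trio,
    random_intervals,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_all", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "simulate": {
        "trio": {
            "chrom_length": 310_000,
            "n_target_fixed": 400,
            "n_sister_fixed": 300,
            "n_shared_polymorphic": 150,
            "indel_blocks": [[120_000, 400], [250_000, 250]],
            "blacklist_regions": [[60_000, 61_000]],
        },
        "atlas": {
            "n_elements": 300,
            "element_length": 500,
            "spacing": 1000,
        },
        "features": {"n_per_class": 40, "length": 200},
        "brain": {"n": 15, "length": 400},
        "skeleton": {"n": 30, "length": 400},
        "score_track": {"shift": 1.0, "noise_sd": 0.5},
        "measurements": {"n_individuals": 8},
    },
    "divergence": {
        "standard_length": 500,
        "maf_threshold": 0.05,
        "min_identity": 0.25,
        "identity_rule": "and",
    },
    "sharing_profile": {"min_combination_size": 5},
    "feature_classes": ["HAR", "hCONDEL", "HAQER", "inversion", "SDR"],
}


def _merge(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML file."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    return config


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Writer:
    """Writes tables with a uniform provenance header."""

    def __init__(self, outdir: Path, seed: int, cfg_hash: str):
        self.outdir = outdir
        self.header = (
            f"# autopod {__version__}; seed={seed}; config=sha256:{cfg_hash}\n"
        )

    def table(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(self.header)
            df.to_csv(fh, sep="\t", index=index)
        return path


def _demo_sharing_spec(conditions):
    """Mixture used by the demo: broadly shared, axis-restricted, and
    single-tissue combinations."""
    hand_early = [c for c in conditions if c.limb == "hand" and c.timepoint == "early"]
    foot_all = [c for c in conditions if c.limb == "foot"]
    phal_late = [c for c in conditions if c.region == "phalanges" and c.timepoint == "late"]
    single = [c for c in conditions if c.tissue == ("foot", "V", "phalanges")]
    return [
        (list(conditions), 0.35),
        (hand_early, 0.2),
        (foot_all, 0.2),
        (phal_late, 0.15),
        (single, 0.1),
    ]


def run_all(config: Mapping[str, Any], out_dir, seed: int | None = None) -> Path:
    """Run every stage on simulated inputs and write all reports."""
    config = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        config["seed"] = int(seed)
    master_seed = int(config["seed"])
    cfg_hash = _config_hash(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out, master_seed, cfg_hash)
    seeds = np.random.SeedSequence(master_seed).generate_state(8)
    sim = config["simulate"]

    # ---------------------------------------------------------- simulation
    logger.info("stage simulate: trio, atlas, features, measurements")
    trio_cfg = sim["trio"]
    trio = simulate_trio(
        TrioSimulationParams(
            chrom_length=int(trio_cfg["chrom_length"]),
            n_target_fixed=int(trio_cfg["n_target_fixed"]),
            n_sister_fixed=int(trio_cfg["n_sister_fixed"]),
            n_shared_polymorphic=int(trio_cfg["n_shared_polymorphic"]),
            indel_blocks=[tuple(b) for b in trio_cfg["indel_blocks"]],
            blacklist_regions=[tuple(b) for b in trio_cfg["blacklist_regions"]],
            seed=int(seeds[0]),
        )
    )
    inputs = out / "inputs"
    trio.write(inputs, chain_dialect="both")

    conditions = autopod_conditions()
    atlas_cfg = sim["atlas"]
    chrom_length = int(trio_cfg["chrom_length"])
    elements, atlas = simulate_atlas(
        n_elements=int(atlas_cfg["n_elements"]),
        conditions=conditions,
        sharing_spec=_demo_sharing_spec(conditions),
        seed=int(seeds[1]),
        element_length=int(atlas_cfg["element_length"]),
        spacing=int(atlas_cfg["spacing"]),
        chrom_length=chrom_length,
    )
    atlas.to_files(inputs / "elements.bed", inputs / "accessibility.tsv")

    brain_set = random_intervals(
        int(sim["brain"]["n"]), chrom_length, int(sim["brain"]["length"]),
        seed=int(seeds[2]), label="brain",
    )
    skeleton_set = random_intervals(
        int(sim["skeleton"]["n"]), chrom_length, int(sim["skeleton"]["length"]),
        seed=int(seeds[3]), label="skeleton",
    )
    write_bed(brain_set, inputs / "brain.bed")
    write_bed(skeleton_set, inputs / "skeleton.bed")

    feature_sets = []
    for i, cls in enumerate(config["feature_classes"]):
        fs = FeatureSet(
            cls,
            random_intervals(
                int(sim["features"]["n_per_class"]), chrom_length,
                int(sim["features"]["length"]),
                seed=int(seeds[4]) + i, label=cls,
            ),
        )
        write_bed(fs.intervals, inputs / f"features_{cls}.bed")
        feature_sets.append(fs)

    measurements = simulate_measurements(
        seed=int(seeds[5]), n_individuals=int(sim["measurements"]["n_individuals"])
    )
    measurements.to_csv(inputs / "measurements.csv", index=False)

    # --------------------------------------------------------------- atlas
    logger.info("stage atlas: %d elements before brain filtering", atlas.n_elements)
    filtered = brain_filter(atlas, brain_set)
    logger.info("stage atlas: %d elements after brain filtering", filtered.n_elements)
    specificity = classify_specificity(filtered, [skeleton_set])
    writer.table(specificity.reset_index(names="element"), "specificity.tsv")

    autopod_specific = filtered.subset(specificity["autopod_specific"].to_numpy())
    partition_rows = []
    element_sets: dict[str, IntervalSet] = {"all_filtered": filtered.elements}
    for axis in ("limb", "region", "timepoint"):
        part = partition_by_axis(autopod_specific, axis)
        for name, subset in part.subsets().items():
            partition_rows.append(
                {"axis": axis, "subset": name, "n_elements": len(subset)}
            )
            element_sets[f"{axis}_{name}"] = subset
    writer.table(pd.DataFrame(partition_rows), "partitions.tsv")

    profile = sharing_profile(
        filtered, int(config["sharing_profile"]["min_combination_size"])
    )
    profile_df = pd.DataFrame(
        [
            {"n_early": k[0], "n_late": k[1], "n_elements": v}
            for k, v in sorted(profile.items())
        ]
    )
    writer.table(profile_df, "sharing_profile.tsv")

    # ------------------------------------------------------------- overlap
    logger.info("stage overlap: %d element sets × %d feature classes",
                len(element_sets), len(feature_sets))
    writer.table(overlap_report(element_sets, feature_sets), "overlaps.tsv")
    chrom_lengths = trio.target.lengths
    flank_rows = []
    for fs in feature_sets:
        if fs.feature_class not in ("inversion", "SDR"):
            continue
        counts = flanking_feature_report(
            filtered.elements, fs, chrom_lengths, widths=(5_000, 10_000)
        )
        for width, n in counts.items():
            flank_rows.append(
                {"feature_class": fs.feature_class, "width": width, "n_elements": n}
            )
    writer.table(pd.DataFrame(flank_rows), "flanking_overlaps.tsv")

    # ---------------------------------------------------------- divergence
    div_cfg = DivergenceConfig(**config["divergence"])
    context = TrioContext(
        target=trio.target,
        sister=trio.sister,
        outgroup=trio.outgroup,
        chain_to_sister=trio.chain_to_sister,
        chain_to_outgroup=trio.chain_to_outgroup,
        catalogs=trio.catalogs,
        blacklist=trio.blacklist,
    )
    reports = run_divergence(element_sets, context, div_cfg)
    div_rows = []
    for label, per_lineage in reports.items():
        for lineage, rep in per_lineage.items():
            div_rows.append(
                {
                    "element_set": label,
                    "lineage": lineage,
                    "bp_surveyed": rep.bp_surveyed,
                    "derived_count": rep.derived_count,
                    "rate_per_bp": rep.rate_per_bp if rep.rate_per_bp is not None else "NA",
                    "rejections": ";".join(
                        f"{k}={v}" for k, v in sorted(rep.rejections.items())
                    ),
                }
            )
    writer.table(pd.DataFrame(div_rows), "divergence.tsv")

    # Conservation shift: plant a mean shift at target-derived positions,
    # background at sister-derived positions, then test for it.
    sc_cfg = sim["score_track"]
    all_rep = reports["all_filtered"]
    t_pos = [p for _, p in all_rep["target"].derived_positions]
    s_pos = [p for _, p in all_rep["sister"].derived_positions]
    if t_pos and s_pos:
        track = simulate_score_track(
            constrained_positions=t_pos,
            shift=float(sc_cfg["shift"]),
            noise_sd=float(sc_cfg["noise_sd"]),
            seed=int(seeds[6]),
            background_positions=s_pos,
        )
        track.to_bedgraph(inputs / "scores.bedgraph")
        shift = conservation_shift_test(
            track.scores_at("chr1", t_pos), track.scores_at("chr1", s_pos)
        )
        writer.table(
            pd.DataFrame(
                [
                    {
                        "mean_target": shift.mean_a,
                        "mean_sister": shift.mean_b,
                        "p_value": shift.p_value,
                        "n_target": shift.n_a,
                        "n_sister": shift.n_b,
                        "n_missing": shift.n_missing,
                    }
                ]
            ),
            "conservation_shift.tsv",
        )
    else:
        logger.info("stage divergence: no derived positions; shift test skipped")

    # ---------------------------------------------------------- enrichment
    cells = {}
    enr_rows = []
    for label, elems in element_sets.items():
        for fs in feature_sets:
            cell = per_bp_rate(elems, fs)
            cells[(label, fs.feature_class)] = cell
            enr_rows.append(
                {
                    "element_set": label,
                    "signal": fs.feature_class,
                    "count": cell.overlap_count,
                    "set_bp": cell.set_bp,
                    "rate_per_bp": cell.rate,
                }
            )
        for species, cat in trio.catalogs.items():
            cell = snp_rate(elems, cat, div_cfg.maf_threshold)
            enr_rows.append(
                {
                    "element_set": label,
                    "signal": cell.feature_class,
                    "count": cell.overlap_count,
                    "set_bp": cell.set_bp,
                    "rate_per_bp": cell.rate,
                }
            )
    writer.table(pd.DataFrame(enr_rows), "enrichment_rates.tsv")

    pair_rows = []
    pairs = [
        ("limb_hand_only", "limb_foot_only"),
        ("region_phalanges_only", "region_metapodial_only"),
        ("timepoint_early_only", "timepoint_late_only"),
    ]
    for a, b in pairs:
        for fs in feature_sets:
            ca, cb = cells.get((a, fs.feature_class)), cells.get((b, fs.feature_class))
            if ca is None or cb is None or ca.set_bp == 0 or cb.set_bp == 0:
                continue
            cmp = compare_pair(ca, cb)
            pair_rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "signal": fs.feature_class,
                    "rate_ratio": cmp.rate_ratio if cmp.rate_ratio is not None else "NA",
                    "p_value": cmp.p_value,
                    "test": cmp.test,
                }
            )
    writer.table(pd.DataFrame(pair_rows), "enrichment_pairs.tsv")

    # ------------------------------------------------------------- anatomy
    pooled = combine_phalanges(measurements)
    report = percent_change(pooled, "human", "chimpanzee")
    writer.table(report, "percent_change.tsv")

    # -------------------------------------------------------------- checks
    writer.table(worked_examples(), "worked_examples.tsv")
    logger.info("run complete: outputs in %s", out)
    return out
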