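"""Interspecific percent change on skeletal measurement tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_measurements",
    "combine_phalanges",
    "percent_change",
]

logger = logging.getLogger(__name__)

LIMBS = ("hand", "foot")
DIGITS = ("I", "II", "III", "IV", "V")
ELEMENTS = ("metapodial", "proximal_phalanx", "middle_phalanx")
DIMENSIONS = ("length", "width")

REQUIRED_COLUMNS = (
    "species",
    "individual",
    "limb",
    "digit",
    "element",
    "dimension",
    "value",
)

_STRATA = ["limb", "digit", "element", "dimension"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (table["value"] <= 0).any():
        raise ValueError("measurement values must be positive")
    return table


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV with the canonical columns."""
    return _validate(pd.read_csv(path))


def combine_phalanges(table: pd.DataFrame) -> pd.DataFrame:
    """Pool proximal and middle phalanx records into one ``phalanges``
    stratum per digit (raw measurements pooled before any averaging).
    Digit I, which has no middle phalanx, passes through unchanged."""
    _validate(table)
    out = table.copy()
    out["element"] = out["element"].replace(
        {"proximal_phalanx": "phalanges", "middle_phalanx": "phalanges"}
    )
    return out


def percent_change(
    table: pd.DataFrame, species_num: str, species_den: str
) -> pd.DataFrame:
    """Per (limb, digit, element, dimension) stratum:
    ``mean(species_num) / mean(species_den) × 100``.

    Strata where either species has no records are reported with a NaN
    percent and flagged in the ``missing`` column.
    """
    _validate(table)
    for sp in (species_num, species_den):
        if sp not in set(table["species"]):
            raise ValueError(f"species {sp!r} absent from the table")
    means = (
        table.groupby(_STRATA + ["species"], sort=True)["value"]
        .mean()
        .unstack("species")
    )
    num = means.get(species_num)
    den = means.get(species_den)
    percent = num / den * 100.0
    out = percent.rename("percent").reset_index()
    out["missing"] = out["percent"].isna()
    n_missing = int(out["missing"].sum())
    if n_missing:
        logger.warning("%d strata missing one or both species", n_missing)
    return out
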