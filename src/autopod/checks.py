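"""Bundled worked-example arithmetic checks.

The inputs are published summary counts shipped as fixtures; each check
recomputes the derived quantity with package code and compares it to the
published value.
"""

from __future__ import annotations

import pandas as pd

from .overlap import expected_differential_count

__all__ = ["worked_examples"]


def _fraction_pct(numerator: int, denominator: int) -> float:
    return round(numerator / denominator * 100.0, 1)


# (name, computation, inputs shown in the report, expected value)
_CHECKS = (
    (
        "har_all_expected_differential",
        lambda: expected_differential_count(474, 1 / 3),
        "474 × 1/3",
        158,
    ),
    (
        "hcondel_all_expected_differential",
        lambda: expected_differential_count(886, 0.08),
        "886 × 0.08",
        71,
    ),
    (
        "har_autopod_expected_differential",
        lambda: expected_differential_count(75, 1 / 3),
        "75 × 1/3",
        25,
    ),
    (
        "hcondel_autopod_expected_differential",
        lambda: expected_differential_count(157, 0.08),
        "157 × 0.08",
        13,
    ),
    (
        "autopod_specific_shared_fraction_pct",
        lambda: _fraction_pct(2654, 12488),
        "2654 / 12488 × 100",
        21.3,
    ),
    (
        "timepoint_deg_total",
        lambda: 1453 + 1578,
        "1453 + 1578",
        3031,
    ),
)


def worked_examples() -> pd.DataFrame:
    """Recompute every bundled arithmetic check and report pass/fail."""
    rows = []
    for name, fn, inputs, expected in _CHECKS:
        computed = fn()
        rows.append(
            {
                "check": name,
                "inputs": inputs,
                "expected": expected,
                "computed": computed,
                "passed": computed == expected,
            }
        )
    return pd.DataFrame(rows)
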