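"""Percent-spliced-in (PSI) per event per condition from pooled counts.

Replicates within a condition are pooled by summing inclusion and exclusion
junction reads per event before computing PSI = 100 * inclusion / (inclusion
+ exclusion). Pooling weights replicates by their coverage, which stabilizes
the estimate for unevenly covered events; events whose pooled coverage falls
below ``min_coverage`` get a missing PSI in that condition.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

#: pooled reads required per event per condition before PSI is reported
DEFAULT_MIN_COVERAGE = 10

COUNT_COLUMNS = ["event_id", "gene", "event_type", "sample_id", "inclusion", "exclusion"]
PSI_COLUMNS = [
    "event_id", "gene", "event_type", "condition",
    "pooled_inclusion", "pooled_exclusion", "coverage", "psi",
]


def _check_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    unknown = set(counts["sample_id"]) - set(design["sample_id"])
    if unknown:
        raise ValueError(f"samples absent from the design table: {sorted(unknown)}")


def merge_group_counts(counts: pd.DataFrame, design: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Sum inclusion/exclusion counts over a condition's samples, per event.

    Returns a frame with columns ``event_id, pooled_inclusion,
    pooled_exclusion``; raises if the condition is unknown or has no samples.
    """
    _check_design(counts, design)
    samples = design.loc[design["condition"] == condition, "sample_id"]
    if samples.empty:
        raise ValueError(f"condition {condition!r} has no samples in the design")
    sub = counts[counts["sample_id"].isin(samples)]
    pooled = (
        sub.groupby("event_id", sort=True)[["inclusion", "exclusion"]]
        .sum()
        .rename(columns={"inclusion": "pooled_inclusion", "exclusion": "pooled_exclusion"})
        .reset_index()
    )
    return pooled


def compute_psi(pooled_inclusion, pooled_exclusion, min_coverage: int = DEFAULT_MIN_COVERAGE):
    """PSI in percent, or NaN where pooled coverage is below ``min_coverage``.

    Accepts scalars or aligned arrays; counts must be nonnegative.
    """
    inc = np.asarray(pooled_inclusion, dtype=float)
    exc = np.asarray(pooled_exclusion, dtype=float)
    if np.any(inc < 0) or np.any(exc < 0):
        raise ValueError("counts must be nonnegative")
    coverage = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(coverage >= min_coverage, 100.0 * inc / np.where(coverage > 0, coverage, 1.0), np.nan)
    if isinstance(pooled_inclusion, numbers.Number) and isinstance(pooled_exclusion, numbers.Number):
        return float(psi)
    return psi


def build_psi_table(counts: pd.DataFrame, design: pd.DataFrame,
                    min_coverage: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """One row per (event, condition) with pooled counts, coverage, and PSI.

    Event metadata (gene, event type) is carried through from the count
    table. Sample order never affects the result.
    """
    _check_design(counts, design)
    merged = counts.merge(design, on="sample_id", how="left", validate="many_to_one")
    pooled = (
        merged.groupby(["event_id", "condition"], sort=True, observed=True)
        .agg(
            gene=("gene", "first"),
            event_type=("event_type", "first"),
            pooled_inclusion=("inclusion", "sum"),
            pooled_exclusion=("exclusion", "sum"),
        )
        .reset_index()
    )
    pooled["coverage"] = pooled["pooled_inclusion"] + pooled["pooled_exclusion"]
    pooled["psi"] = compute_psi(
        pooled["pooled_inclusion"].to_numpy(),
        pooled["pooled_exclusion"].to_numpy(),
        min_coverage=min_coverage,
    )
    return pooled[PSI_COLUMNS]
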