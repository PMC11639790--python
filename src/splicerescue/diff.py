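"""Differential splicing between two conditions on pooled counts.

For each event covered in both conditions the change in percent-spliced-in
(dPSI = PSI_test - PSI_ref) is paired with a two-sided Fisher exact test on
the 2x2 table of pooled inclusion/exclusion counts. P-values are adjusted
per comparison with the Benjamini-Hochberg step-up procedure, and an event
is called significant when |dPSI| strictly exceeds the threshold (default 15
percent) AND the adjusted p-value is strictly below alpha (default 0.05).

The exact test on pooled counts is the package's reconstruction of a
junction-count comparison after replicate pooling; the test name is recorded
in the output so alternative statistics can be slotted in behind the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import EVENT_TYPES

DEFAULT_DPSI_THRESHOLD = 15.0
DEFAULT_ALPHA = 0.05
DEFAULT_SWEEP_THRESHOLDS = (10.0, 15.0, 20.0, 25.0)

TEST_NAME = "fisher_exact_pooled"

DIFF_COLUMNS = [
    "event_id", "event_type", "psi_ref", "psi_test", "dpsi", "p_raw", "p_adj", "significant",
]


@dataclass
class DiffTable:
    """Result of one pairwise comparison.

    ``table`` has one row per event with coverage in both conditions and
    columns ``event_id, event_type, psi_ref, psi_test, dpsi, p_raw, p_adj,
    significant``. The significance rule is recomputable from the stored
    columns plus the threshold and alpha recorded here.
    """

    reference: str
    test: str
    dpsi_threshold: float
    alpha: float
    table: pd.DataFrame
    test_name: str = TEST_NAME

    @property
    def label(self) -> str:
        return f"{self.reference} vs {self.test}"


def event_test(inc_ref: int, exc_ref: int, inc_test: int, exc_test: int) -> float:
    """Two-sided Fisher exact p-value for [[inc_ref, exc_ref], [inc_test, exc_test]].

    Both condition totals must be positive (coverage filtering upstream
    guarantees this in the pipeline).
    """
    if min(inc_ref, exc_ref, inc_test, exc_test) < 0:
        raise ValueError("counts must be nonnegative")
    if inc_ref + exc_ref < 1 or inc_test + exc_test < 1:
        raise ValueError("each condition needs at least one read (zero-coverage row)")
    return float(stats.fisher_exact([[inc_ref, exc_ref], [inc_test, exc_test]],
                                    alternative="two-sided").pvalue)


def adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pivot_pair(psi_table: pd.DataFrame, reference: str, test: str) -> pd.DataFrame:
    present = set(psi_table["condition"])
    for cond in (reference, test):
        if cond not in present:
            raise ValueError(f"condition {cond!r} not present in the PSI table")
    ref = psi_table[psi_table["condition"] == reference].set_index("event_id")
    tst = psi_table[psi_table["condition"] == test].set_index("event_id")
    shared = ref.join(tst, how="inner", lsuffix="_ref", rsuffix="_test")
    shared = shared[shared["psi_ref"].notna() & shared["psi_test"].notna()]
    if shared.empty:
        raise ValueError(
            f"no events with coverage in both {reference!r} and {test!r}"
        )
    return shared.sort_index()


def compare_groups(psi_table: pd.DataFrame, reference: str, test: str,
                   dpsi_threshold: float = DEFAULT_DPSI_THRESHOLD,
                   alpha: float = DEFAULT_ALPHA) -> DiffTable:
    """Differential-splicing table for ``reference`` vs ``test``.

    Events lacking coverage in either condition are dropped from this
    comparison only. dPSI is signed test minus reference.
    """
    shared = _pivot_pair(psi_table, reference, test)
    p_raw = np.array([
        event_test(ir, er, it, et)
        for ir, er, it, et in zip(
            shared["pooled_inclusion_ref"], shared["pooled_exclusion_ref"],
            shared["pooled_inclusion_test"], shared["pooled_exclusion_test"],
        )
    ])
    p_adj = adjust_pvalues(p_raw)
    dpsi = (shared["psi_test"] - shared["psi_ref"]).to_numpy()
    table = pd.DataFrame(
        {
            "event_id": shared.index,
            "event_type": shared["event_type_ref"].to_numpy(),
            "psi_ref": shared["psi_ref"].to_numpy(),
            "psi_test": shared["psi_test"].to_numpy(),
            "dpsi": dpsi,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": (np.abs(dpsi) > dpsi_threshold) & (p_adj < alpha),
        }
    ).reset_index(drop=True)
    return DiffTable(reference=reference, test=test, dpsi_threshold=float(dpsi_threshold),
                     alpha=float(alpha), table=table)


def threshold_sweep(psi_table: pd.DataFrame, comparisons, thresholds=DEFAULT_SWEEP_THRESHOLDS,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Count significant events per comparison at each dPSI cut point.

    The exact tests are run once per comparison and reused across
    thresholds. Returns a tidy frame with columns ``comparison, reference,
    test, dpsi_threshold, n_significant`` plus one ``n_<type>`` column per
    event type.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must not be empty")
    rows = []
    for reference, test in comparisons:
        diff = compare_groups(psi_table, reference, test, dpsi_threshold=0.0, alpha=alpha)
        t = diff.table
        for thr in thresholds:
            sig = t[(t["dpsi"].abs() > thr) & (t["p_adj"] < alpha)]
            row = {
                "comparison": diff.label,
                "reference": reference,
                "test": test,
                "dpsi_threshold": float(thr),
                "n_significant": int(len(sig)),
            }
            type_counts = sig["event_type"].value_counts()
            for et in EVENT_TYPES:
                row[f"n_{et}"] = int(type_counts.get(et, 0))
            rows.append(row)
    return pd.DataFrame(rows)


def tally_event_types(diff: DiffTable) -> dict:
    """Counts of significant events per splice-event type."""
    sig = diff.table[diff.table["significant"]]
    unknown = set(sig["event_type"]) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")
    counts = sig["event_type"].value_counts()
    return {et: int(counts.get(et, 0)) for et in EVENT_TYPES}
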