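"""Three-comparison rescue classification of altered features.

Given alteration tables for the three pairwise contrasts of a
control/disease/treated-disease design —

* CD: control vs disease (disease effect),
* DT: disease vs treated disease (treatment effect),
* CT: control vs treated disease (residual difference after treatment),

— every feature is assigned exactly one class from its significance pattern
(sig_CD, sig_DT, sig_CT) and, where it matters, the direction of its effects:

====================  =========================================================
pattern               class
====================  =========================================================
(1, 1, 0) contrary    ``fully_recovered`` — the treatment moved the feature
                      back and no control-vs-treated difference remains
(1, 1, 0) same        ``aggravated`` — treatment pushed further in the disease
                      direction (yet no residual difference was detected)
(1, 1, 1)             ``non_specific`` — changed by treatment without
                      restoring the control state
(1, 0, 1)             ``disease_persistent``
(1, 0, 0)             ``disease_unresponsive``
(0, 1, *)             ``treatment_only`` — treatment-induced novelty
(0, 0, 1)             ``residual_only``
(0, 0, 0)             ``not_altered``
====================  =========================================================

The classifier is generic over the effect measure: dPSI in percent for
splicing, log2 fold change for expression — only the sign and the
significance flag matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .diff import DiffTable

CLASSES = (
    "fully_recovered",
    "non_specific",
    "aggravated",
    "disease_persistent",
    "disease_unresponsive",
    "treatment_only",
    "residual_only",
    "not_altered",
)

VENN_REGIONS = ("CD_only", "DT_only", "CT_only", "CD_DT", "CD_CT", "DT_CT", "CD_DT_CT")


@dataclass
class AlterationTable:
    """One comparison's per-feature effects: generic over splicing/expression.

    ``table`` columns: ``feature_id`` (unique), ``effect`` (signed; dPSI or
    log2FC), ``significant`` (bool). A significant feature must have a
    nonzero effect.
    """

    label: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"feature_id", "effect", "significant"} - set(t.columns)
        if missing:
            raise ValueError(f"alteration table {self.label!r} lacks columns {sorted(missing)}")
        if t["feature_id"].duplicated().any():
            dup = t.loc[t["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValueError(f"duplicate feature_id {dup!r} in alteration table {self.label!r}")
        bad = t["significant"] & (t["effect"].isna() | (t["effect"] == 0))
        if bad.any():
            fid = t.loc[bad, "feature_id"].iloc[0]
            raise ValueError(
                f"feature {fid!r} is significant with zero/missing effect in {self.label!r}"
            )


@dataclass
class ComparisonTriple:
    """The three aligned alteration tables of the rescue design."""

    alt_cd: AlterationTable
    alt_dt: AlterationTable
    alt_ct: AlterationTable

    def merged(self) -> pd.DataFrame:
        """Outer-joined per-feature frame over the union feature universe.

        Missing features count as not significant in that comparison; their
        effect is NaN.
        """
        frames = []
        for key, alt in (("cd", self.alt_cd), ("dt", self.alt_dt), ("ct", self.alt_ct)):
            f = alt.table[["feature_id", "effect", "significant"]].rename(
                columns={"effect": f"effect_{key}", "significant": f"sig_{key}"}
            )
            frames.append(f.set_index("feature_id"))
        merged = frames[0].join(frames[1:], how="outer")
        for key in ("cd", "dt", "ct"):
            col = merged[f"sig_{key}"]
            merged[f"sig_{key}"] = np.where(col.isna(), False, col).astype(bool)
        return merged.sort_index()


def diff_to_alteration(diff: DiffTable) -> AlterationTable:
    """Adapt a differential-splicing table: effect = dPSI."""
    t = diff.table
    out = pd.DataFrame(
        {
            "feature_id": t["event_id"].to_numpy(),
            "effect": t["dpsi"].to_numpy(),
            "significant": t["significant"].to_numpy(),
        }
    )
    out = out[out["effect"].notna()].reset_index(drop=True)
    return AlterationTable(label=diff.label, table=out)


def expression_to_alteration(rows: pd.DataFrame, fc_threshold: float = 1.0,
                             alpha: float = 0.05, label: str = "expression") -> AlterationTable:
    """Adapt a differential-expression table (gene, log2fc, p_adj).

    A gene is significantly altered when |log2FC| strictly exceeds
    ``fc_threshold`` and its adjusted p-value is strictly below ``alpha``.
    """
    required = {"gene", "log2fc", "p_adj"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"expression table lacks columns {sorted(missing)}")
    log2fc = pd.to_numeric(rows["log2fc"], errors="coerce")
    p_adj = pd.to_numeric(rows["p_adj"], errors="coerce")
    bad = log2fc.isna() | ~np.isfinite(log2fc) | p_adj.isna() | (p_adj < 0) | (p_adj > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"malformed expression row {row}: log2fc={rows['log2fc'].iloc[row]!r}, "
                         f"p_adj={rows['p_adj'].iloc[row]!r}")
    significant = (log2fc.abs() > fc_threshold) & (p_adj < alpha)
    out = pd.DataFrame(
        {
            "feature_id": rows["gene"].to_numpy(),
            "effect": log2fc.to_numpy(),
            "significant": significant.to_numpy(),
        }
    )
    return AlterationTable(label=label, table=out)


def direction_concordance(effect_cd: float, effect_dt: float) -> str:
    """``"contrary"`` if the two effects have opposite signs, else ``"same"``.

    Zero effects are rejected: a significant feature cannot have a zero
    effect, so a zero here signals an upstream bug.
    """
    if effect_cd == 0 or effect_dt == 0:
        raise ValueError("direction is undefined for a zero effect")
    return "contrary" if np.sign(effect_cd) * np.sign(effect_dt) < 0 else "same"


def classify_events(triple: ComparisonTriple) -> pd.DataFrame:
    """Label every feature in the triple's universe with exactly one class.

    Returns a frame with columns ``feature_id, label`` sorted by feature_id.
    """
    m = triple.merged()
    cd, dt, ct = m["sig_cd"].to_numpy(), m["sig_dt"].to_numpy(), m["sig_ct"].to_numpy()

    labels = np.empty(len(m), dtype=object)
    labels[~cd & ~dt & ~ct] = "not_altered"
    labels[~cd & ~dt & ct] = "residual_only"
    labels[~cd & dt] = "treatment_only"
    labels[cd & ~dt & ~ct] = "disease_unresponsive"
    labels[cd & ~dt & ct] = "disease_persistent"
    labels[cd & dt & ct] = "non_specific"

    both = cd & dt & ~ct
    if both.any():
        e_cd = m["effect_cd"].to_numpy()[both]
        e_dt = m["effect_dt"].to_numpy()[both]
        if np.any(np.isnan(e_cd)) or np.any(np.isnan(e_dt)):
            fid = m.index[both][np.isnan(e_cd) | np.isnan(e_dt)][0]
            raise ValueError(f"feature {fid!r} significant but missing an effect")
        directions = [direction_concordance(a, b) for a, b in zip(e_cd, e_dt)]
        labels[both] = np.where(
            np.array(directions) == "contrary", "fully_recovered", "aggravated"
        )
    return pd.DataFrame({"feature_id": m.index.to_numpy(), "label": labels})


def _round_half_away(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


@dataclass
class RescueReport:
    """Class counts, Venn-region counts, and recovery percentages.

    Percentages use the number of CD-significant features as denominator and
    are stored unrounded; :meth:`to_dict` renders them to one decimal
    (half-away-from-zero). They are ``None`` when no feature is
    CD-significant.
    """

    class_counts: dict
    venn_counts: dict
    n_features: int
    n_cd_significant: int
    full_recovery_pct: float | None
    non_specific_pct: float | None
    treatment_specific_count: int

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_cd_significant": self.n_cd_significant,
            "class_counts": dict(self.class_counts),
            "venn_counts": dict(self.venn_counts),
            "full_recovery_pct": None if self.full_recovery_pct is None
            else _round_half_away(self.full_recovery_pct),
            "non_specific_pct": None if self.non_specific_pct is None
            else _round_half_away(self.non_specific_pct),
            "treatment_specific_count": self.treatment_specific_count,
        }


def summarize_rescue(labels: pd.DataFrame, triple: ComparisonTriple) -> RescueReport:
    """Aggregate per-feature labels into a rescue report.

    ``treatment_specific_count`` is |fully_recovered| + |non_specific| — the
    features whose change is attributable to the treatment acting on the
    disease state.
    """
    m = triple.merged()
    if set(labels["feature_id"]) != set(m.index):
        raise ValueError("labels do not cover the triple's feature universe")
    lc = labels["label"].value_counts()
    class_counts = {c: int(lc.get(c, 0)) for c in CLASSES}

    cd, dt, ct = m["sig_cd"].to_numpy(), m["sig_dt"].to_numpy(), m["sig_ct"].to_numpy()
    venn_counts = {
        "CD_only": int(np.sum(cd & ~dt & ~ct)),
        "DT_only": int(np.sum(~cd & dt & ~ct)),
        "CT_only": int(np.sum(~cd & ~dt & ct)),
        "CD_DT": int(np.sum(cd & dt & ~ct)),
        "CD_CT": int(np.sum(cd & ~dt & ct)),
        "DT_CT": int(np.sum(~cd & dt & ct)),
        "CD_DT_CT": int(np.sum(cd & dt & ct)),
    }
    n_cd = int(np.sum(cd))
    if n_cd > 0:
        full_pct = 100.0 * class_counts["fully_recovered"] / n_cd
        nonspec_pct = 100.0 * class_counts["non_specific"] / n_cd
    else:
        full_pct = nonspec_pct = None
    return RescueReport(
        class_counts=class_counts,
        venn_counts=venn_counts,
        n_features=int(len(m)),
        n_cd_significant=n_cd,
        full_recovery_pct=full_pct,
        non_specific_pct=nonspec_pct,
        treatment_specific_count=class_counts["fully_recovered"] + class_counts["non_specific"],
    )


def rank_recovered(labels: pd.DataFrame, triple: ComparisonTriple, k: int = 10) -> pd.DataFrame:
    """Top-k fully recovered features by descending |effect_CD|.

    Ties break lexicographically on feature_id, so the ranking is stable
    across runs. Returns fewer than k rows when fewer exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = triple.merged()
    recovered = labels.loc[labels["label"] == "fully_recovered", "feature_id"]
    sub = m.loc[m.index.isin(recovered)].copy()
    sub["abs_effect_cd"] = sub["effect_cd"].abs()
    sub = sub.sort_index().sort_values("abs_effect_cd", ascending=False, kind="stable")
    out = sub.head(k).reset_index().rename(columns={"index": "feature_id"})
    return out[["feature_id", "effect_cd", "effect_dt", "abs_effect_cd"]]
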