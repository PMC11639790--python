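"""Synthetic three-condition splice-event count data with known ground truth.

Emulates the statistical structure of a control / disease / treated-disease
splicing study: each alternative-splicing event has a true percent-spliced-in
(PSI) per condition, a fraction of events is altered in disease, a
sub-fraction of those is restored (fully or halfway) by treatment, and a
small fraction of unaffected events is perturbed only by the treatment.
Observed inclusion/exclusion junction counts are drawn per sample with
binomial or beta-binomial noise around the true PSI.

Ground-truth class sizes are deterministic functions of the configuration
(rounded products, assigned after a seeded shuffle), so the label
composition of a dataset is reproducible from the config alone; only the
counts carry sampling noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("CTRL", "DM1", "DM1_MP")
EVENT_TYPES = ("ES", "IR", "Alt3", "Alt5")
STATUSES = (
    "null",
    "disease_rescued_full",
    "disease_rescued_partial",
    "disease_unrescued",
    "treatment_only",
)

#: default mix of event types: exon skipping dominates, as in typical
#: junction-based event catalogs.
DEFAULT_EVENT_TYPE_MIX = {"ES": 0.5, "IR": 0.2, "Alt3": 0.15, "Alt5": 0.15}


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration; names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic three-condition dataset.

    Fractions are of the event universe (``frac_disease``), of the
    disease-altered events (``frac_rescued``, ``frac_partial``) or of the
    non-disease events (``frac_treatment_only``). ``min_true_dpsi`` is the
    minimum |true dPSI| in percent for any altered event. ``overdispersion``
    is the beta-binomial rho in [0, 1); 0 gives pure binomial counts.
    """

    n_events: int = 1000
    n_replicates: int = 3
    frac_disease: float = 0.2
    frac_rescued: float = 0.17
    frac_partial: float = 0.1
    frac_treatment_only: float = 0.02
    min_true_dpsi: float = 20.0
    mean_depth: float = 100.0
    overdispersion: float = 0.05
    event_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_TYPE_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_events, (int, np.integer)) and self.n_events >= 1):
            raise ConfigurationError(f"n_events must be a positive integer, got {self.n_events!r}")
        if not (isinstance(self.n_replicates, (int, np.integer)) and self.n_replicates >= 1):
            raise ConfigurationError(
                f"n_replicates must be a positive integer, got {self.n_replicates!r}"
            )
        for name in ("frac_disease", "frac_rescued", "frac_partial", "frac_treatment_only"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.frac_rescued + self.frac_partial > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_rescued + frac_partial must not exceed 1, got "
                f"{self.frac_rescued} + {self.frac_partial}"
            )
        # baseline PSIs live in [5, 95]; an effect of magnitude <= 50 always
        # fits on at least one side, so 50 bounds the realizable minimum.
        if not (0.0 < self.min_true_dpsi <= 50.0):
            raise ConfigurationError(
                f"min_true_dpsi must lie in (0, 50] percent, got {self.min_true_dpsi!r}"
            )
        if not self.mean_depth > 0:
            raise ConfigurationError(f"mean_depth must be positive, got {self.mean_depth!r}")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ConfigurationError(
                f"overdispersion must lie in [0, 1), got {self.overdispersion!r}"
            )
        if set(self.event_type_mix) != set(EVENT_TYPES):
            raise ConfigurationError(
                f"event_type_mix must have keys {EVENT_TYPES}, got {sorted(self.event_type_mix)}"
            )
        if abs(sum(self.event_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("event_type_mix must sum to 1")
        if any(v < 0 for v in self.event_type_mix.values()):
            raise ConfigurationError("event_type_mix proportions must be nonnegative")

    def class_sizes(self) -> dict:
        """Deterministic ground-truth class sizes implied by the config."""
        n_disease = _round_half_up(self.n_events * self.frac_disease)
        n_full = _round_half_up(n_disease * self.frac_rescued)
        n_partial = min(_round_half_up(n_disease * self.frac_partial), n_disease - n_full)
        n_unrescued = n_disease - n_full - n_partial
        n_trt = _round_half_up((self.n_events - n_disease) * self.frac_treatment_only)
        n_null = self.n_events - n_disease - n_trt
        return {
            "null": n_null,
            "disease_rescued_full": n_full,
            "disease_rescued_partial": n_partial,
            "disease_unrescued": n_unrescued,
            "treatment_only": n_trt,
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def sample_event_counts(true_psi, depth, overdispersion, rng):
    """Draw (inclusion, exclusion) junction counts for one or more events.

    ``inclusion ~ Binomial(depth, true_psi/100)`` when ``overdispersion`` is
    0; otherwise the success probability is itself drawn from a Beta
    distribution with mean ``true_psi/100`` and correlation parameter rho =
    ``overdispersion`` (beta-binomial). Accepts scalars or aligned arrays.
    """
    psi = np.asarray(true_psi, dtype=float)
    depth = np.asarray(depth)
    if np.any(psi < 0) or np.any(psi > 100):
        raise ValueError(f"true_psi must lie in [0, 100], got {true_psi!r}")
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1")
    p = psi / 100.0
    if overdispersion == 0:
        inclusion = rng.binomial(depth, p)
    else:
        shape = 1.0 / overdispersion - 1.0
        # Beta is degenerate at p in {0, 1}: keep those probabilities fixed.
        interior = (p > 0) & (p < 1)
        p_draw = np.array(p, dtype=float, copy=True)
        if np.any(interior):
            a = np.where(interior, p * shape, 1.0)
            b = np.where(interior, (1.0 - p) * shape, 1.0)
            draws = rng.beta(a, b)
            p_draw = np.where(interior, draws, p_draw)
        inclusion = rng.binomial(depth, p_draw)
    exclusion = depth - inclusion
    if np.isscalar(true_psi) and np.isscalar(depth):
        return int(inclusion), int(exclusion)
    return inclusion, exclusion


def _assign_true_psis(config: SimulationConfig, rng: np.random.Generator):
    """Status labels, event types, and true per-condition PSIs for all events."""
    n = config.n_events
    sizes = config.class_sizes()

    order = rng.permutation(n)
    status = np.empty(n, dtype=object)
    cursor = 0
    for name in ("disease_rescued_full", "disease_rescued_partial",
                 "disease_unrescued", "treatment_only", "null"):
        k = sizes[name]
        status[order[cursor:cursor + k]] = name
        cursor += k

    # event types: largest-remainder apportionment, then a seeded shuffle,
    # so the type composition is also exact given the config.
    quotas = np.array([config.event_type_mix[t] * n for t in EVENT_TYPES])
    base = np.floor(quotas).astype(int)
    rem = n - base.sum()
    frac_order = np.argsort(-(quotas - base), kind="stable")
    base[frac_order[:rem]] += 1
    types = np.repeat(np.array(EVENT_TYPES, dtype=object), base)
    types = types[rng.permutation(n)]

    base_psi = rng.uniform(5.0, 95.0, size=n)
    # effect magnitudes capped at 50 so at least one direction always fits
    # inside [0, 100] for baselines in [5, 95]
    hi = min(config.min_true_dpsi + 15.0, 50.0)
    mag = rng.uniform(config.min_true_dpsi, hi, size=n)
    sign = rng.choice(np.array([-1.0, 1.0]), size=n)
    sign = np.where(base_psi + sign * mag > 100.0, -np.abs(sign), sign)
    sign = np.where(base_psi + sign * mag < 0.0, np.abs(sign), sign)
    shifted = base_psi + sign * mag

    psi_ctrl = base_psi.copy()
    psi_dm1 = base_psi.copy()
    psi_trt = base_psi.copy()

    diseased = np.isin(status, ("disease_rescued_full", "disease_rescued_partial",
                                "disease_unrescued"))
    psi_dm1[diseased] = shifted[diseased]
    psi_trt[status == "disease_unrescued"] = shifted[status == "disease_unrescued"]
    partial = status == "disease_rescued_partial"
    psi_trt[partial] = 0.5 * (psi_ctrl[partial] + psi_dm1[partial])
    trt_only = status == "treatment_only"
    psi_trt[trt_only] = shifted[trt_only]

    return status, types, psi_ctrl, psi_dm1, psi_trt


def simulate_dataset(config: SimulationConfig):
    """Generate a synthetic dataset.

    Returns ``(counts, design, truth)``:

    counts
        Long-format frame with columns ``event_id, gene, event_type,
        sample_id, inclusion, exclusion``.
    design
        Frame with columns ``sample_id, condition``.
    truth
        One row per event: ``event_id, event_type, status,
        true_psi_control, true_psi_dm1, true_psi_treated``.

    Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    status, types, psi_ctrl, psi_dm1, psi_trt = _assign_true_psis(config, rng)

    width = len(str(n))
    event_ids = np.array([f"EV{i + 1:0{width}d}" for i in range(n)], dtype=object)
    genes = np.array([f"GENE{i + 1:0{width}d}" for i in range(n)], dtype=object)

    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "event_type": types,
            "status": status,
            "true_psi_control": psi_ctrl,
            "true_psi_dm1": psi_dm1,
            "true_psi_treated": psi_trt,
        }
    )

    true_by_condition = {"CTRL": psi_ctrl, "DM1": psi_dm1, "DM1_MP": psi_trt}
    design_rows = []
    count_blocks = []
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{condition}_{rep}"
            design_rows.append((sample_id, condition))
            depth = np.maximum(rng.poisson(config.mean_depth, size=n), 1)
            inc, exc = sample_event_counts(
                true_by_condition[condition], depth, config.overdispersion, rng
            )
            count_blocks.append(
                pd.DataFrame(
                    {
                        "event_id": event_ids,
                        "gene": genes,
                        "event_type": types,
                        "sample_id": sample_id,
                        "inclusion": inc.astype(np.int64),
                        "exclusion": exc.astype(np.int64),
                    }
                )
            )

    counts = pd.concat(count_blocks, ignore_index=True)
    design = pd.DataFrame(design_rows, columns=["sample_id", "condition"])
    return counts, design, truth


def write_fixture(counts: pd.DataFrame, design: pd.DataFrame, truth: pd.DataFrame,
                  directory) -> dict:
    """Write counts/design/ground-truth TSVs readable by :mod:`splicerescue.io`.

    Returns a dict of written paths. Refuses empty tables.
    """
    from . import io as srio

    if counts.empty or design.empty or truth.empty:
        raise ValueError("refusing to write an empty dataset fixture")
    missing = set(truth["event_id"]) ^ set(counts["event_id"])
    if missing:
        raise ValueError(f"counts and ground truth disagree on event_ids: {sorted(missing)[:5]}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "design": directory / "design.tsv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    srio.write_table(counts, paths["counts"])
    srio.write_table(design, paths["design"])
    srio.write_table(truth, paths["ground_truth"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["event_type_mix"] = dict(config.event_type_mix)
    return d
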