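"""End-to-end pipeline: simulate/load -> PSI -> three comparisons -> rescue report.

The pipeline runs the three-way rescue design: it quantifies pooled PSI per
condition, calls differential splicing for control-vs-disease (CD),
disease-vs-treated (DT), and control-vs-treated (CT), sweeps the dPSI cut
points, classifies every event's response to treatment, and writes all
intermediates plus a JSON report and a run manifest. Given the same
configuration (including seed) the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, io as srio
from .diff import (DEFAULT_ALPHA, DEFAULT_DPSI_THRESHOLD, DEFAULT_SWEEP_THRESHOLDS,
                   compare_groups, threshold_sweep)
from .psi import DEFAULT_MIN_COVERAGE, build_psi_table
from .rescue import (ComparisonTriple, RescueReport, classify_events,
                     diff_to_alteration, rank_recovered, summarize_rescue)
from .simulate import ConfigurationError, SimulationConfig, config_to_dict, simulate_dataset

logger = logging.getLogger("splicerescue")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``counts_path``/``design_path`` point at existing TSVs, or
    ``simulation`` provides a :class:`SimulationConfig` to generate them.
    ``conditions`` names the (control, disease, treated) triple in the design.
    """

    outdir: str | Path
    counts_path: str | Path | None = None
    design_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    dpsi_threshold: float = DEFAULT_DPSI_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    min_coverage: int = DEFAULT_MIN_COVERAGE
    sweep_thresholds: tuple = DEFAULT_SWEEP_THRESHOLDS
    conditions: tuple = ("CTRL", "DM1", "DM1_MP")
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if len(set(self.conditions)) != 3:
            raise ConfigurationError(
                f"the three condition labels must be distinct, got {self.conditions!r}"
            )
        if not self.sweep_thresholds:
            raise ConfigurationError("sweep_thresholds must not be empty")
        for t in self.sweep_thresholds:
            if not (0.0 < t <= 100.0):
                raise ConfigurationError(
                    f"sweep thresholds must lie in (0, 100], got {t!r}"
                )
        if not (0.0 < self.dpsi_threshold <= 100.0):
            raise ConfigurationError(
                f"dpsi_threshold must lie in (0, 100], got {self.dpsi_threshold!r}"
            )
        has_files = self.counts_path is not None and self.design_path is not None
        if not has_files and self.simulation is None:
            raise ConfigurationError(
                "provide counts_path+design_path or a simulation config"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "sweep_thresholds" in raw:
            raw["sweep_thresholds"] = tuple(raw["sweep_thresholds"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "simulation"}
        d["outdir"] = str(self.outdir)
        d["counts_path"] = None if self.counts_path is None else str(self.counts_path)
        d["design_path"] = None if self.design_path is None else str(self.design_path)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        d["conditions"] = list(self.conditions)
        d["simulation"] = None if self.simulation is None else config_to_dict(self.simulation)
        return d


def _configure_logging(verbosity: int) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> RescueReport:
    """Run every stage and write all outputs under ``config.outdir``.

    Writes: counts/design (and ground truth, when simulated), the PSI table,
    one differential table per comparison, the threshold sweep, per-event
    class labels, the top recovered events, ``report.json`` and
    ``manifest.json``. Returns the :class:`~splicerescue.rescue.RescueReport`.
    """
    _configure_logging(config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "dpsi_threshold": config.dpsi_threshold,
        "alpha": config.alpha,
        "min_coverage": config.min_coverage,
        "seed": config.seed,
    }
    input_checksums = {}

    if config.counts_path is not None and config.design_path is not None:
        counts = _stage("read_counts")(srio.read_table)(config.counts_path, "counts")
        design = _stage("read_design")(srio.read_table)(config.design_path, "design")
        input_checksums["counts"] = srio.sha256_of(config.counts_path)
        input_checksums["design"] = srio.sha256_of(config.design_path)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        counts, design, truth = _stage("simulate")(simulate_dataset)(sim)
        srio.write_table(counts, outdir / "counts.tsv", metadata=params)
        srio.write_table(design, outdir / "design.tsv", metadata=params)
        srio.write_table(truth, outdir / "ground_truth.tsv", metadata=params)
    logger.info("events read: %d (%d count rows, %d samples)",
                counts["event_id"].nunique(), len(counts), len(design))

    psi_table = _stage("psi")(build_psi_table)(counts, design, min_coverage=config.min_coverage)
    srio.write_table(psi_table, outdir / "psi.tsv", metadata=params)
    logger.info("PSI rows with coverage: %d / %d", int(psi_table["psi"].notna().sum()),
                len(psi_table))

    ctrl, dm1, treated = config.conditions
    comparisons = [(ctrl, dm1), (dm1, treated), (ctrl, treated)]
    diffs = {}
    for ref, test in comparisons:
        diff = _stage(f"diff_{ref}_vs_{test}")(compare_groups)(
            psi_table, ref, test,
            dpsi_threshold=config.dpsi_threshold, alpha=config.alpha,
        )
        srio.write_diff_table(diff, outdir / f"diff_{ref}_vs_{test}.tsv",
                              extra_metadata=input_checksums)
        diffs[(ref, test)] = diff
        logger.info("%s: %d / %d events significant", diff.label,
                    int(diff.table["significant"].sum()), len(diff.table))

    sweep = _stage("sweep")(threshold_sweep)(
        psi_table, comparisons, thresholds=config.sweep_thresholds, alpha=config.alpha
    )
    srio.write_table(sweep, outdir / "sweep.tsv", metadata=params)

    triple = ComparisonTriple(
        alt_cd=diff_to_alteration(diffs[(ctrl, dm1)]),
        alt_dt=diff_to_alteration(diffs[(dm1, treated)]),
        alt_ct=diff_to_alteration(diffs[(ctrl, treated)]),
    )
    labels = _stage("classify")(classify_events)(triple)
    srio.write_table(labels, outdir / "labels.tsv", metadata=params)
    report = _stage("summarize")(summarize_rescue)(labels, triple)
    logger.info("class counts: %s", report.class_counts)

    top = rank_recovered(labels, triple, k=10)
    srio.write_table(top, outdir / "top_recovered.tsv", metadata=params)

    report_payload = {"parameters": params, "comparisons": [list(c) for c in comparisons],
                      **report.to_dict()}
    (outdir / "report.json").write_text(
        json.dumps(report_payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest = {
        "tool": "splicerescue",
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": input_checksums,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
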