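"""End-to-end orchestration: calibrate, simulate, re-express, report.

``run_full_analysis`` chains the stages: cell-free calibration (plastic
sorption + degradation), with-cells calibration (cell and plastic rates,
degradation fixed), trajectory simulation of every exposure scenario and
nominal concentration appearing in the viability data, dose-metric
computation, and per-metric 4PL re-expression into an IC50 summary table.
Every output file carries a provenance header (package version, seed,
config hash) and the whole run is deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import KineticDataset, fit_cell_free, fit_with_cells
from .dosimetry import METRIC_NAMES, compute_dose_metrics, dose_metric_table
from .dose_response import reexpress_dose_response
from .kinetics import (
    AssaySetup,
    ExposureScenario,
    acute_scenario,
    repeated_scenario,
    solve_piecewise_exact,
    washout_scenario,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "build_scenarios", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name travels with the error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ScenarioSpec:
    """Declarative scenario: label, kind and schedule (hours)."""

    label: str
    kind: str  # acute | repeated | washout
    end_time: float
    dose_times: tuple[float, ...] = (0.0, 48.0, 120.0)
    washout_times: tuple[float, ...] = (168.0, 216.0, 288.0)

    def build(self, nominal_um: float, setup: AssaySetup) -> ExposureScenario:
        if self.kind == "acute":
            return acute_scenario(nominal_um, self.end_time, setup, label=self.label)
        if self.kind == "repeated":
            return repeated_scenario(
                nominal_um, setup, self.dose_times, self.end_time, label=self.label
            )
        if self.kind == "washout":
            return washout_scenario(
                nominal_um, setup, self.dose_times, self.washout_times, self.end_time, label=self.label
            )
        raise ValueError(f"unknown scenario kind {self.kind!r}")


#: The study's four exposure scenarios plus the acute kinetic-sampling arm.
DEFAULT_SCENARIO_SPECS = (
    ScenarioSpec("24 h", "acute", 24.0),
    ScenarioSpec("48 h", "acute", 48.0),
    ScenarioSpec("7 d", "repeated", 168.0),
    ScenarioSpec("7 dW", "washout", 336.0),
    ScenarioSpec("acute", "acute", 336.0),
)


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run (YAML-serialisable)."""

    cellfree_csv: str
    withcells_csv: str
    viability_csv: str
    outdir: str
    seed: int = 0
    medium_volume_ml: float = 2.0
    cells_per_well: float = 2_000_000.0
    n_starts: int = 8
    fit_max_time_h: float | None = None
    fit_nominals: tuple[float, ...] | None = None
    fix_kdeg: bool = True
    fix_plastic: bool = False
    constrain_top: float | None = None
    constrain_bottom: float | None = None
    metrics: tuple[str, ...] = METRIC_NAMES
    scenario_specs: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIO_SPECS

    @property
    def setup(self) -> AssaySetup:
        return AssaySetup(self.medium_volume_ml, self.cells_per_well)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        specs = tuple(
            ScenarioSpec(
                label=s["label"],
                kind=s["kind"],
                end_time=float(s["end_time"]),
                dose_times=tuple(s.get("dose_times", (0.0, 48.0, 120.0))),
                washout_times=tuple(s.get("washout_times", (168.0, 216.0, 288.0))),
            )
            for s in raw.pop("scenarios", [])
        ) or DEFAULT_SCENARIO_SPECS
        for key in ("fit_nominals", "metrics"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(scenario_specs=specs, **raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_scenarios(
    specs, setup: AssaySetup, nominal_um: float = 1.0
) -> dict[str, ExposureScenario]:
    """Label-keyed scenario templates at the given nominal concentration."""
    return {spec.label: spec.build(nominal_um, setup) for spec in specs}


def _provenance_write(df: pd.DataFrame, path: Path, config_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# invitrokin {__version__}  config={config_hash}  seed={seed}\n")
        df.to_csv(fh, index=False)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run calibration -> simulation -> dose metrics -> re-expression.

    Returns a bundle with the two fit results, the dose-metric table, the
    IC50 table per metric, and the paths of everything written.  Any stage
    failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup = config.setup
    chash = config.config_hash()
    scenarios = build_scenarios(config.scenario_specs, setup)
    log_lines = [f"invitrokin {__version__} run, config hash {chash}, seed {config.seed}"]
    t_start = time.perf_counter()

    def stage(name):
        logger.info("stage %s", name)
        log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] stage {name}")

    try:
        stage("load")
        cellfree = KineticDataset.from_csv(config.cellfree_csv)
        withcells = KineticDataset.from_csv(config.withcells_csv)
        viability = pd.read_csv(config.viability_csv, comment="#")
    except Exception as e:
        raise StageError("load", e)

    if config.fit_max_time_h is not None or config.fit_nominals is not None:
        withcells_fit = withcells.filter(
            max_time=config.fit_max_time_h, nominals=config.fit_nominals
        )
    else:
        withcells_fit = withcells

    try:
        stage("fit_cell_free")
        cf = fit_cell_free(
            cellfree, setup, scenarios, n_starts=config.n_starts, seed=config.seed
        )
        log_lines.append(cf.summary())
    except Exception as e:
        raise StageError("fit_cell_free", e)

    try:
        stage("fit_with_cells")
        fixed = {}
        if config.fix_kdeg:
            fixed["kdeg"] = cf.params.kdeg
        if config.fix_plastic:
            fixed["ka_plastic"] = cf.params.ka_plastic
            fixed["kd_plastic"] = cf.params.kd_plastic
        wc = fit_with_cells(
            withcells_fit, fixed, setup, scenarios, n_starts=config.n_starts, seed=config.seed
        )
        log_lines.append(wc.summary())
    except Exception as e:
        raise StageError("fit_with_cells", e)

    try:
        stage("simulate+metrics")
        labels = [str(l) for l in viability["scenario_label"].unique()]
        nominals = sorted(float(n) for n in viability["nominal_uM"].unique() if n > 0)
        trajs = {}
        metrics = {}
        for label in labels:
            if label not in scenarios:
                raise ValueError(f"viability scenario {label!r} has no scenario definition")
            for nominal in nominals:
                sc = scenarios[label].with_nominal(nominal, setup.medium_volume_ml)
                grid = np.arange(0.0, sc.end_time + 0.05, 0.1)
                traj = solve_piecewise_exact(wc.params, sc, grid)
                trajs[(label, nominal)] = traj
                metrics[(label, nominal)] = compute_dose_metrics(traj, setup)
        metric_df = dose_metric_table(trajs, setup)
    except Exception as e:
        raise StageError("simulate+metrics", e)

    try:
        stage("dose_response")
        ic50_rows = []
        fits = {}
        for metric in config.metrics:
            mfits, table = reexpress_dose_response(
                viability,
                metrics,
                metric,
                constrain_top=config.constrain_top,
                constrain_bottom=config.constrain_bottom,
            )
            fits[metric] = mfits
            ic50_rows.append(table)
        ic50_df = pd.concat(ic50_rows, ignore_index=True)
    except Exception as e:
        raise StageError("dose_response", e)

    stage("write")
    params_df = pd.DataFrame(
        [
            {"stage": "cell_free", **{n: getattr(cf.params, n) for n in cf.params._NAMES},
             "objective": cf.objective_value, "converged": cf.converged},
            {"stage": "with_cells", **{n: getattr(wc.params, n) for n in wc.params._NAMES},
             "objective": wc.objective_value, "converged": wc.converged},
        ]
    )
    paths = {
        "parameters": outdir / "parameters.csv",
        "residuals": outdir / "residuals.csv",
        "dose_metrics": outdir / "dose_metrics.csv",
        "ic50_table": outdir / "ic50_table.csv",
        "run_log": outdir / "run_log.txt",
    }
    _provenance_write(params_df, paths["parameters"], chash, config.seed)
    _provenance_write(wc.residual_table, paths["residuals"], chash, config.seed)
    _provenance_write(metric_df, paths["dose_metrics"], chash, config.seed)
    _provenance_write(ic50_df, paths["ic50_table"], chash, config.seed)
    log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] done")
    paths["run_log"].write_text("\n".join(log_lines) + "\n")

    return {
        "fit_cell_free": cf,
        "fit_with_cells": wc,
        "dose_metrics": metric_df,
        "ic50_table": ic50_df,
        "fits": fits,
        "paths": {k: str(v) for k, v in paths.items()},
        "config_hash": chash,
    }
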