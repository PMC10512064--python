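"""Rate-constant estimation from compartment measurements.

The rate constants of the compartment model are estimated by minimising a
normalised squared-error objective against observed compartment amounts.
Residuals are relative (normalised to the observed value) and re-weighted so
that every sampling time point contributes equal total weight, balancing the
dense early sampling against the sparse late points:

    J(theta) = sum_i w_i * ((pred_i - obs_i) / obs_i)**2,   w_i = 1 / n(t_i)

where n(t_i) counts all included observations sharing the time point t_i,
across nominal concentrations, compartments and replicates.

Estimation is two-stage: the cell-free system (medium + plastic only) pins
down plastic sorption/desorption and the abiotic degradation rate, then the
with-cells system is fitted with the degradation rate fixed and the cell and
plastic rates free.  Optimisation is quasi-Newton (BFGS) on log-transformed
rates, which enforces positivity without penalty terms, with a seeded
log-uniform multi-start because the objective is not convex.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from scipy.linalg import expm

from .kinetics import (
    AssaySetup,
    ExposureScenario,
    RateParameters,
    _segments,
    solve_piecewise_exact,
)

__all__ = [
    "QUANTIFICATION_FLOOR",
    "Observation",
    "KineticDataset",
    "FitResult",
    "FoldErrorReport",
    "KineticRateFitter",
    "objective",
    "fit_cell_free",
    "fit_with_cells",
    "predict_fold_errors",
]

logger = logging.getLogger(__name__)

#: Observations below this amount (nmol) are excluded from relative
#: residuals, which are unstable near zero.
QUANTIFICATION_FLOOR = 1e-3

DATASET_COLUMNS = (
    "system",
    "scenario_label",
    "nominal_uM",
    "compartment",
    "time_h",
    "replicate",
    "amount_nmol",
)

_SYSTEMS = ("with_cells", "cell_free")


@dataclass(frozen=True)
class Observation:
    """One destructively sampled compartment measurement."""

    system: str
    nominal_concentration: float
    scenario_label: str
    compartment: str
    time: float
    replicate: int
    amount: float


@dataclass
class KineticDataset:
    """Observed compartment amounts with replicate structure.

    Wraps a DataFrame with columns ``system, scenario_label, nominal_uM,
    compartment, time_h, replicate, amount_nmol``.  ``inclusion_filter`` is a
    human-readable description of how the dataset was restricted.
    """

    frame: pd.DataFrame
    inclusion_filter: str = "all observations"

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"kinetic dataset is missing columns: {sorted(missing)}")
        f = self.frame.reset_index(drop=True)
        if len(f) == 0:
            raise ValueError("kinetic dataset is empty")
        bad = ~f["system"].isin(_SYSTEMS)
        if bad.any():
            raise ValueError(f"unknown system values: {sorted(f.loc[bad, 'system'].unique())}")
        if (f["amount_nmol"] < 0).any():
            raise ValueError("amounts must be >= 0")
        cellfree_cells = (f["system"] == "cell_free") & (f["compartment"] == "cells")
        if cellfree_cells.any():
            raise ValueError("cell-free observations cannot have compartment == 'cells'")
        self.frame = f

    @classmethod
    def from_csv(cls, path, inclusion_filter: str | None = None) -> "KineticDataset":
        frame = pd.read_csv(path, comment="#")
        return cls(frame, inclusion_filter or f"loaded from {path}")

    @classmethod
    def from_observations(cls, obs: Sequence[Observation], inclusion_filter: str = "all observations") -> "KineticDataset":
        frame = pd.DataFrame(
            {
                "system": [o.system for o in obs],
                "scenario_label": [o.scenario_label for o in obs],
                "nominal_uM": [o.nominal_concentration for o in obs],
                "compartment": [o.compartment for o in obs],
                "time_h": [o.time for o in obs],
                "replicate": [o.replicate for o in obs],
                "amount_nmol": [o.amount for o in obs],
            }
        )
        return cls(frame, inclusion_filter)

    def filter(
        self,
        system: str | None = None,
        max_time: float | None = None,
        nominals: Sequence[float] | None = None,
        scenario_labels: Sequence[str] | None = None,
        compartments: Sequence[str] | None = None,
    ) -> "KineticDataset":
        f = self.frame
        desc = [self.inclusion_filter]
        if system is not None:
            f = f[f["system"] == system]
            desc.append(f"system={system}")
        if max_time is not None:
            f = f[f["time_h"] <= max_time]
            desc.append(f"time<={max_time}h")
        if nominals is not None:
            f = f[f["nominal_uM"].isin(list(nominals))]
            desc.append(f"nominal in {list(nominals)}")
        if scenario_labels is not None:
            f = f[f["scenario_label"].isin(list(scenario_labels))]
            desc.append(f"scenario in {list(scenario_labels)}")
        if compartments is not None:
            f = f[f["compartment"].isin(list(compartments))]
            desc.append(f"compartment in {list(compartments)}")
        return KineticDataset(f.reset_index(drop=True), "; ".join(desc))

    def __len__(self) -> int:
        return len(self.frame)


def resolve_scenario(
    scenarios: Mapping, label: str, nominal: float, setup: AssaySetup
) -> ExposureScenario:
    """Look up (label, nominal) in a scenario mapping.

    The mapping may be keyed by (label, nominal) pairs or by label alone; a
    label-keyed template is rescaled to the requested nominal (the dosing
    schedule is shared across concentrations, only the dose amounts scale).
    """
    if (label, nominal) in scenarios:
        return scenarios[(label, nominal)]
    if label not in scenarios:
        raise ValueError(f"no scenario definition for label {label!r} (nominal {nominal} µM)")
    return scenarios[label].with_nominal(nominal, setup.medium_volume_ml)


_COMP_INDEX = {"medium": 0, "cells": 1, "plastic": 2}


def predict_amounts(
    params: RateParameters,
    frame: pd.DataFrame,
    setup: AssaySetup,
    scenarios: Mapping,
) -> np.ndarray:
    """Model-predicted amount for every observation row.

    Cell-free rows are predicted with the cell exchange rates zeroed (the
    two-compartment reduction of the same model).  At a medium-exchange time
    the pre-event value is used: a destructively sampled well is terminated
    before its refresh.
    """
    pred = np.empty(len(frame))
    for (system, label, nominal), idx in frame.groupby(
        ["system", "scenario_label", "nominal_uM"], sort=False
    ).groups.items():
        scenario = resolve_scenario(scenarios, label, nominal, setup)
        p = params if system == "with_cells" else params.replace(ka_cell=0.0, kd_cell=0.0)
        times = frame.loc[idx, "time_h"].to_numpy(dtype=float)
        traj = solve_piecewise_exact(p, scenario, np.unique(times))
        comps = frame.loc[idx, "compartment"].map(_COMP_INDEX).to_numpy()
        states = np.stack([traj.at(t, event_phase="pre") for t in times])
        pred[frame.index.get_indexer(idx)] = states[np.arange(len(times)), comps]
    return pred


def _states_at(params: RateParameters, scenario: ExposureScenario, times: np.ndarray) -> np.ndarray:
    """Lean exact solver: [medium, cells, plastic] at sorted unique times.

    Pre-event values at medium-exchange times (destructive sampling).  Used
    in the optimisation hot loop where building a full Trajectory would
    dominate the run time.
    """
    A = params.augmented_matrix()
    cache: dict[float, np.ndarray] = {}

    def step(y: np.ndarray, h: float) -> np.ndarray:
        E = cache.get(h)
        if E is None:
            E = expm(A * h)
            cache[h] = E
        return E @ y

    y = np.zeros(4)
    out = np.empty((len(times), 3))
    i = 0
    for t0, t1, med_after in _segments(scenario):
        while i < len(times) and abs(times[i] - t0) < 1e-9:
            out[i] = y[:3]
            i += 1
        y = y.copy()
        y[0] = med_after
        prev = t0
        while i < len(times) and times[i] < t1 - 1e-9:
            y = step(y, times[i] - prev)
            prev = times[i]
            out[i] = y[:3]
            i += 1
        y = step(y, t1 - prev)
    while i < len(times) and abs(times[i] - scenario.end_time) < 1e-9:
        out[i] = y[:3]
        i += 1
    if i != len(times):
        raise ValueError(
            f"query time {times[i]} outside scenario {scenario.label!r} horizon"
        )
    return out


@dataclass
class _PreparedObjective:
    """Pre-resolved group structure so repeated objective calls skip pandas."""

    groups: list
    obs: np.ndarray
    weights: np.ndarray

    def __call__(self, params: RateParameters) -> float:
        pred = np.empty(len(self.obs))
        for cellfree, scenario, uniq, inv, comp_idx, positions in self.groups:
            p = params.replace(ka_cell=0.0, kd_cell=0.0) if cellfree else params
            states = _states_at(p, scenario, uniq)
            pred[positions] = states[inv, comp_idx]
        r = (pred - self.obs) / self.obs
        return float(np.sum(self.weights * r * r))


def _prepare_objective(
    frame: pd.DataFrame, setup: AssaySetup, scenarios: Mapping, floor: float
) -> _PreparedObjective:
    keep = _included(frame, floor)
    if not keep.any():
        raise ValueError("all observations fall below the quantification floor")
    sub = frame[keep].reset_index(drop=True)
    obs = sub["amount_nmol"].to_numpy(dtype=float)
    w = 1.0 / sub.groupby("time_h")["time_h"].transform("size").to_numpy(dtype=float)
    groups = []
    for (system, label, nominal), idx in sub.groupby(
        ["system", "scenario_label", "nominal_uM"], sort=False
    ).groups.items():
        scenario = resolve_scenario(scenarios, label, nominal, setup)
        times_arr = sub.loc[idx, "time_h"].to_numpy(dtype=float)
        uniq, inv = np.unique(times_arr, return_inverse=True)
        comp_idx = sub.loc[idx, "compartment"].map(_COMP_INDEX).to_numpy()
        groups.append((system == "cell_free", scenario, uniq, inv, comp_idx, idx.to_numpy()))
    return _PreparedObjective(groups, obs, w)


def _included(frame: pd.DataFrame, floor: float) -> pd.Series:
    keep = frame["amount_nmol"] >= floor
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("excluded %d observation(s) below the %.g nmol floor", n_dropped, floor)
    return keep


def objective(
    params: RateParameters,
    dataset: KineticDataset,
    setup: AssaySetup,
    scenarios: Mapping,
    floor: float = QUANTIFICATION_FLOOR,
) -> float:
    """Time-point-balanced sum of squared relative prediction errors."""
    return _prepare_objective(dataset.frame, setup, scenarios, floor)(params)


@dataclass
class FitResult:
    """Outcome of one calibration stage."""

    params: RateParameters
    objective_value: float
    converged: bool
    n_starts: int
    residual_table: pd.DataFrame
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def fold_errors(self) -> pd.Series:
        return self.residual_table["fold_error"]

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"objective = {self.objective_value:.10g}  converged = {self.converged}  starts = {self.n_starts}\n")
        for name in RateParameters._NAMES:
            tag = " (fixed)" if name in self.fixed else ""
            buf.write(f"  {name:12s} = {getattr(self.params, name):.8g} /h{tag}\n")
        fe = self.fold_errors
        buf.write(f"  fold error: median {fe.median():.4g}, max {fe.max():.4g} over {len(fe)} obs\n")
        return buf.getvalue()


_LOG_CLIP = (-30.0, 6.0)


class KineticRateFitter(BaseEstimator):
    """Estimator for the compartment-model rate constants.

    Parameters
    ----------
    stage : {"with_cells", "cell_free"}
        ``cell_free`` fits (ka_plastic, kd_plastic, kdeg) on the
        medium/plastic reduction with the cell rates pinned to zero;
        ``with_cells`` fits all rates not listed in ``fixed``.
    fixed : dict, optional
        Rate constants pinned at given values (typically ``{"kdeg": ...}``
        carried over from the cell-free stage).
    n_starts, seed, start_low, start_high :
        Multi-start configuration: ``n_starts`` BFGS runs from starting
        points drawn log-uniformly from [start_low, start_high] /h with a
        seeded generator.
    setup, scenarios :
        Assay geometry and the scenario definitions the observations refer
        to (mapping of label or (label, nominal) to ExposureScenario).

    Attributes (after ``fit``)
    --------------------------
    params_ : RateParameters
    objective_value_ : float
    converged_ : bool
    result_ : FitResult
    """

    def __init__(
        self,
        setup: AssaySetup | None = None,
        scenarios: Mapping | None = None,
        stage: str = "with_cells",
        fixed: dict | None = None,
        n_starts: int = 8,
        seed: int = 0,
        start_low: float = 1e-4,
        start_high: float = 1.0,
        floor: float = QUANTIFICATION_FLOOR,
    ):
        self.setup = setup
        self.scenarios = scenarios
        self.stage = stage
        self.fixed = fixed
        self.n_starts = n_starts
        self.seed = seed
        self.start_low = start_low
        self.start_high = start_high
        self.floor = floor

    def _free_and_fixed(self) -> tuple[list[str], dict[str, float]]:
        fixed = dict(self.fixed or {})
        for name, value in fixed.items():
            if name not in RateParameters._NAMES:
                raise ValueError(f"unknown rate constant {name!r}")
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"fixed {name} must be finite and >= 0")
        if self.stage == "cell_free":
            fixed.setdefault("ka_cell", 0.0)
            fixed.setdefault("kd_cell", 0.0)
        elif self.stage != "with_cells":
            raise ValueError(f"unknown stage {self.stage!r}")
        free = [n for n in RateParameters._NAMES if n not in fixed]
        if not free:
            raise ValueError("no free parameters left to fit")
        return free, fixed

    def fit(self, dataset: KineticDataset) -> "KineticRateFitter":
        setup = self.setup or AssaySetup()
        if self.scenarios is None:
            raise ValueError("scenarios mapping is required")
        free, fixed = self._free_and_fixed()
        if self.stage == "cell_free" and (dataset.frame["system"] != "cell_free").any():
            raise ValueError("cell_free stage expects a dataset of cell_free observations only")

        def make_params(z: np.ndarray) -> RateParameters:
            rates = dict(fixed)
            for name, zi in zip(free, np.clip(z, *_LOG_CLIP)):
                rates[name] = float(np.exp(zi))
            return RateParameters(**rates)

        prepared = _prepare_objective(dataset.frame, setup, self.scenarios, self.floor)

        def fun(z: np.ndarray) -> float:
            return prepared(make_params(z))

        rng = np.random.default_rng(self.seed)
        lo, hi = np.log(self.start_low), np.log(self.start_high)
        starts = rng.uniform(lo, hi, size=(self.n_starts, len(free)))
        best = None
        any_converged = False
        for z0 in starts:
            res = minimize(fun, z0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
            # BFGS on a noisy finite-difference gradient often stops with a
            # "precision loss" status at a perfectly flat point; accept a
            # start whose final gradient is numerically negligible.
            ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4 * max(1.0, abs(res.fun))
            any_converged = any_converged or ok
            if best is None or res.fun < best.fun:
                best = res
        if not any_converged:
            logger.warning("no BFGS start converged; returning the best point found")

        params = make_params(best.x)
        self.params_ = params
        self.objective_value_ = float(best.fun)
        self.converged_ = any_converged
        self.result_ = FitResult(
            params=params,
            objective_value=self.objective_value_,
            converged=any_converged,
            n_starts=self.n_starts,
            residual_table=residual_table(params, dataset, setup, self.scenarios, self.floor),
            fixed=fixed,
        )
        return self


def residual_table(
    params: RateParameters,
    dataset: KineticDataset,
    setup: AssaySetup,
    scenarios: Mapping,
    floor: float = QUANTIFICATION_FLOOR,
) -> pd.DataFrame:
    """Per-observation predictions, normalised residuals and fold errors."""
    frame = dataset.frame.copy()
    frame["included"] = _included(frame, floor)
    frame["predicted_nmol"] = predict_amounts(params, frame, setup, scenarios)
    obs = frame["amount_nmol"].to_numpy()
    pred = frame["predicted_nmol"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(frame["included"], (pred - obs) / obs, np.nan)
        ratio = np.where(frame["included"], pred / obs, np.nan)
        fold = np.where(ratio > 0, np.maximum(ratio, 1.0 / ratio), np.inf)
    frame["relative_residual"] = rel
    frame["fold_error"] = np.where(frame["included"], fold, np.nan)
    n_t = frame.loc[frame["included"]].groupby("time_h")["time_h"].transform("size")
    frame["weight"] = (1.0 / n_t).reindex(frame.index)
    return frame


def fit_cell_free(
    dataset: KineticDataset,
    setup: AssaySetup | None = None,
    scenarios: Mapping | None = None,
    **options,
) -> FitResult:
    """Stage 1: estimate (ka_plastic, kd_plastic, kdeg) from cell-free data."""
    fitter = KineticRateFitter(setup=setup, scenarios=scenarios, stage="cell_free", **options)
    return fitter.fit(dataset).result_

def fit_with_cells(
    dataset: KineticDataset,
    fixed: dict | None = None,
    setup: AssaySetup | None = None,
    scenarios: Mapping | None = None,
    **options,
) -> FitResult:
    """Stage 2: estimate the remaining rates from with-cells data.

    ``fixed`` typically pins ``kdeg`` (and optionally the plastic rates)
    from the cell-free stage.
    """
    fitter = KineticRateFitter(
        setup=setup, scenarios=scenarios, stage="with_cells", fixed=fixed, **options
    )
    return fitter.fit(dataset).result_


@dataclass
class FoldErrorReport:
    """Per-observation fold errors of model predictions on held-out data."""

    table: pd.DataFrame
    median: float
    maximum: float


def predict_fold_errors(
    fit: FitResult | RateParameters,
    holdout: KineticDataset,
    setup: AssaySetup | None = None,
    scenarios: Mapping | None = None,
    floor: float = QUANTIFICATION_FLOOR,
) -> FoldErrorReport:
    """Fold errors max(pred/obs, obs/pred) of a fitted model on held-out data."""
    params = fit.params if isinstance(fit, FitResult) else fit
    setup = setup or AssaySetup()
    table = residual_table(params, holdout, setup, scenarios, floor)
    fe = table.loc[table["included"], "fold_error"]
    if fe.empty:
        raise ValueError("no held-out observations above the quantification floor")
    return FoldErrorReport(table=table, median=float(fe.median()), maximum=float(fe.max()))
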