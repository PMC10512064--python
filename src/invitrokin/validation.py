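"""Predictive-performance protocols for the calibrated compartment model.

The central check: calibrate the model on the *first day* of the 1 µM
single-dose data (plus the cell-free system for the degradation rate) and
ask how well it predicts everything it has not seen - the later time points,
the higher nominal concentration and the repeated-dose/washout scenarios -
as per-observation fold errors max(pred/obs, obs/pred) in the medium and
cell compartments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import fit_cell_free, fit_with_cells, predict_fold_errors
from .kinetics import AssaySetup, acute_scenario, repeated_scenario, washout_scenario
from .synthetic import GroundTruth, generate_kinetics_dataset, paper_kinetics_design

__all__ = ["FoldErrorStudy", "fold_error_simulation_study", "run_two_stage_calibration"]


def _study_scenarios(setup: AssaySetup) -> dict:
    return {
        "acute": acute_scenario(1.0, 336.0, setup, label="acute"),
        "7 d": repeated_scenario(1.0, setup),
        "7 dW": washout_scenario(1.0, setup),
    }


def run_two_stage_calibration(
    cellfree_ds,
    withcells_ds,
    setup: AssaySetup,
    scenarios: dict,
    seed: int = 0,
    n_starts: int = 8,
    fit_max_time_h: float | None = None,
    fit_nominals: tuple[float, ...] | None = None,
):
    """Cell-free stage then with-cells stage (kdeg carried over fixed).

    Returns (cell_free_result, with_cells_result).
    """
    cf = fit_cell_free(cellfree_ds, setup, scenarios, seed=seed, n_starts=n_starts)
    train = withcells_ds.filter(max_time=fit_max_time_h, nominals=fit_nominals)
    wc = fit_with_cells(
        train, {"kdeg": cf.params.kdeg}, setup, scenarios, seed=seed, n_starts=n_starts
    )
    return cf, wc


@dataclass
class FoldErrorStudy:
    """Pooled fold errors over the repetitions of the simulation study."""

    per_repetition_median: list[float]
    fold_errors: np.ndarray  # pooled over repetitions, medium+cells holdout
    n_observations: int

    @property
    def median(self) -> float:
        return float(np.median(self.fold_errors))

    @property
    def maximum(self) -> float:
        return float(np.max(self.fold_errors))


def fold_error_simulation_study(
    truth: GroundTruth,
    n_repetitions: int = 20,
    seed: int = 0,
    setup: AssaySetup | None = None,
    n_starts: int = 8,
) -> FoldErrorStudy:
    """Seeded holdout-prediction study at the study's sampling design.

    Per repetition: generate noisy with-cells datasets for the 1 and 2 µM
    acute arms and the 1 µM repeated/washout arms, plus a 1 µM cell-free
    profile; run the two-stage calibration with the with-cells stage
    restricted to the first 24 h of the 1 µM data; then score fold errors of
    the predicted medium and cell amounts on every held-out observation
    (1 µM beyond 24 h, all of 2 µM, and the repeated/washout collections).
    """
    setup = setup or AssaySetup()
    scenarios = _study_scenarios(setup)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_repetitions, 2))
    per_rep = []
    pooled = []
    for rep in range(n_repetitions):
        cf_seed, wc_seed = map(int, sub_seeds[rep])
        cf_design = {
            "acute": (acute_scenario(1.0, 336.0, setup, label="acute"), truth.sampling_times)
        }
        cellfree = generate_kinetics_dataset(truth, cf_design, False, cf_seed, setup)
        wc_frames = [
            generate_kinetics_dataset(
                truth, paper_kinetics_design(1.0, setup), True, wc_seed, setup
            ).frame,
            generate_kinetics_dataset(
                truth,
                {"acute": (acute_scenario(2.0, 336.0, setup, label="acute"), (1.0, 3.0, 6.0, 24.0, 48.0))},
                True,
                wc_seed + 1,
                setup,
            ).frame,
        ]
        withcells = type(cellfree)(pd.concat(wc_frames, ignore_index=True), "simulation study")

        cf, wc = run_two_stage_calibration(
            cellfree,
            withcells,
            setup,
            scenarios,
            seed=cf_seed % (2**16),
            n_starts=n_starts,
            fit_max_time_h=24.0,
            fit_nominals=(1.0,),
        )

        frame = withcells.frame
        trained = (
            (frame["nominal_uM"] == 1.0)
            & (frame["scenario_label"] == "acute")
            & (frame["time_h"] <= 24.0)
        )
        holdout_frame = frame[~trained & frame["compartment"].isin(["medium", "cells"])]
        holdout = type(cellfree)(holdout_frame.reset_index(drop=True), "holdout")
        report = predict_fold_errors(wc, holdout, setup, scenarios)
        fe = report.table.loc[report.table["included"], "fold_error"].to_numpy()
        pooled.append(fe)
        per_rep.append(float(np.median(fe)))
    pooled_arr = np.concatenate(pooled)
    return FoldErrorStudy(
        per_repetition_median=per_rep,
        fold_errors=pooled_arr,
        n_observations=int(pooled_arr.size),
    )
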