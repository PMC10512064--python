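"""Rate-constant estimation: objective, two-stage fits, fold errors."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from invitrokin import (
    AssaySetup,
    KineticDataset,
    KineticRateFitter,
    RateParameters,
    acute_scenario,
    fit_cell_free,
    fit_with_cells,
    generate_kinetics_dataset,
    objective,
    predict_fold_errors,
    solve_piecewise_exact,
)
from invitrokin.calibration import residual_table
from invitrokin.synthetic import paper_kinetics_design

SETUP = AssaySetup()
TRUE = RateParameters(0.16, 0.14, 0.55, 2.0, 0.004)


def make_dataset(rows):
    return KineticDataset(pd.DataFrame(rows))


def medium_pred(params, scenario, t):
    return solve_piecewise_exact(params, scenario, [t]).at(t)[0]


@pytest.fixture(scope="module")
def scenarios():
    return {"acute": acute_scenario(1.0, 336.0, SETUP, label="acute")}


@pytest.fixture(scope="module")
def noisefree_withcells(truth, study_scenarios):
    t = replace(truth, noise_cv_kinetics=0.0)
    return generate_kinetics_dataset(t, paper_kinetics_design(1.0, SETUP), True, seed=0, setup=SETUP)


def test_objective_is_zero_for_perfect_predictions(truth, study_scenarios):
    t = replace(truth, noise_cv_kinetics=0.0)
    ds = generate_kinetics_dataset(t, paper_kinetics_design(1.0, SETUP), True, seed=0, setup=SETUP)
    assert objective(truth.params, ds, SETUP, study_scenarios) < 1e-12


def test_objective_unit_value_for_twofold_misprediction(scenarios):
    pred = medium_pred(TRUE, scenarios["acute"], 6.0)
    ds = make_dataset(
        [dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
              compartment="medium", time_h=6.0, replicate=0, amount_nmol=pred / 2.0)]
    )
    assert objective(TRUE, ds, SETUP, scenarios) == pytest.approx(1.0, rel=1e-10)


def test_objective_invariant_under_uniform_rescaling(scenarios):
    """Relative residuals: doubling the dose and every observation leaves
    the objective unchanged."""
    rng = np.random.default_rng(3)
    rows = []
    for t in (1.0, 6.0, 24.0):
        for comp in ("medium", "cells"):
            rows.append(dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
                             compartment=comp, time_h=t, replicate=0,
                             amount_nmol=float(rng.uniform(0.1, 1.0))))
    ds1 = make_dataset(rows)
    rows2 = [dict(r, nominal_uM=2.0, amount_nmol=2 * r["amount_nmol"]) for r in rows]
    ds2 = make_dataset(rows2)
    v1 = objective(TRUE, ds1, SETUP, scenarios)
    v2 = objective(TRUE, ds2, SETUP, scenarios)
    assert v1 == pytest.approx(v2, rel=1e-10)


def test_objective_balances_time_points(scenarios):
    """A time point shared by several observations gets weight 1/n each, so
    every sampling time contributes equal total weight."""
    sc = scenarios["acute"]
    p1 = medium_pred(TRUE, sc, 1.0)
    p24 = medium_pred(TRUE, sc, 24.0)
    rows = [
        dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
             compartment="medium", time_h=1.0, replicate=r, amount_nmol=p1 / 2.0)
        for r in range(3)
    ] + [
        dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
             compartment="medium", time_h=24.0, replicate=0, amount_nmol=p24 / 2.0)
    ]
    # each observation has relative residual 1; 3 obs at t=1 share weight
    val = objective(TRUE, make_dataset(rows), SETUP, scenarios)
    assert val == pytest.approx(3 * (1 / 3) + 1 * 1.0, rel=1e-10)


def test_below_floor_observations_are_excluded(scenarios):
    rows = [
        dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
             compartment="cells", time_h=1.0, replicate=0, amount_nmol=5e-4),
    ]
    with pytest.raises(ValueError, match="floor"):
        objective(TRUE, make_dataset(rows), SETUP, scenarios)


def test_cell_free_stage_recovers_plastic_and_degradation_rates(truth, scenarios):
    t = replace(truth, noise_cv_kinetics=0.0)
    design = {"acute": (scenarios["acute"], t.sampling_times)}
    ds = generate_kinetics_dataset(t, design, with_cells=False, seed=0, setup=SETUP)
    res = fit_cell_free(ds, SETUP, scenarios, seed=0)
    assert res.converged
    for name in ("ka_plastic", "kd_plastic", "kdeg"):
        fitted, true = getattr(res.params, name), getattr(truth.params, name)
        assert abs(fitted - true) / true < 0.01
    assert res.params.ka_cell == 0.0 and res.params.kd_cell == 0.0


def test_constant_mass_data_implies_negligible_degradation(scenarios):
    p = TRUE.replace(kdeg=0.0)
    rows = []
    for t in (1.0, 6.0, 24.0, 48.0, 168.0):
        state = solve_piecewise_exact(p.replace(ka_cell=0, kd_cell=0), scenarios["acute"], [t]).at(t)
        rows.append(dict(system="cell_free", scenario_label="acute", nominal_uM=1.0,
                         compartment="medium", time_h=t, replicate=0, amount_nmol=state[0]))
        rows.append(dict(system="cell_free", scenario_label="acute", nominal_uM=1.0,
                         compartment="plastic", time_h=t, replicate=0, amount_nmol=state[2]))
    res = fit_cell_free(make_dataset(rows), SETUP, scenarios, seed=0)
    assert res.params.kdeg < 1e-4


def test_with_cells_stage_recovers_rates_with_kdeg_fixed(truth, study_scenarios, noisefree_withcells):
    res = fit_with_cells(
        noisefree_withcells, {"kdeg": truth.params.kdeg}, SETUP, study_scenarios, seed=0
    )
    assert res.converged
    for name in ("ka_cell", "kd_cell", "ka_plastic", "kd_plastic"):
        fitted, true = getattr(res.params, name), getattr(truth.params, name)
        assert abs(fitted - true) / true < 0.01


def test_objective_at_truth_not_above_fitted_optimum(truth, study_scenarios, noisefree_withcells):
    res = fit_with_cells(
        noisefree_withcells, {"kdeg": truth.params.kdeg}, SETUP, study_scenarios, seed=0
    )
    at_truth = objective(truth.params, noisefree_withcells, SETUP, study_scenarios)
    assert res.objective_value <= at_truth + 1e-9


def test_first_day_fit_extrapolates_to_repeated_dosing(truth, study_scenarios, noisefree_withcells):
    """Calibrating on the first 24 h of the 1 µM data alone still predicts
    the 168/336 h repeated-exposure amounts (noise-free: almost exactly)."""
    train = noisefree_withcells.filter(max_time=24.0, scenario_labels=["acute"])
    res = fit_with_cells(train, {"kdeg": truth.params.kdeg}, SETUP, study_scenarios, seed=0)
    holdout = noisefree_withcells.filter(scenario_labels=["7 d", "7 dW"])
    report = predict_fold_errors(res, holdout, SETUP, study_scenarios)
    assert report.maximum < 1.05


def test_fit_is_deterministic_for_fixed_seed(truth, study_scenarios, noisefree_withcells):
    a = fit_with_cells(noisefree_withcells, {"kdeg": truth.params.kdeg}, SETUP, study_scenarios, seed=7)
    b = fit_with_cells(noisefree_withcells, {"kdeg": truth.params.kdeg}, SETUP, study_scenarios, seed=7)
    assert a.params == b.params
    assert a.objective_value == b.objective_value


def test_fold_errors_trivial_cases(truth, study_scenarios, noisefree_withcells):
    report = predict_fold_errors(truth.params, noisefree_withcells, SETUP, study_scenarios)
    assert report.median == pytest.approx(1.0, abs=1e-9)
    # corrupt one observation to a third of its prediction -> max fold 3
    frame = noisefree_withcells.frame.copy()
    frame.loc[0, "amount_nmol"] = frame.loc[0, "amount_nmol"] / 3.0
    report = predict_fold_errors(truth.params, KineticDataset(frame), SETUP, study_scenarios)
    assert report.maximum == pytest.approx(3.0, rel=1e-9)


def test_residual_table_carries_weights_and_inclusion(truth, study_scenarios, noisefree_withcells):
    table = residual_table(truth.params, noisefree_withcells, SETUP, study_scenarios)
    inc = table[table["included"]]
    assert np.allclose(inc["relative_residual"], 0.0, atol=1e-9)
    # weights sum to the number of distinct time points
    assert inc["weight"].sum() == pytest.approx(inc["time_h"].nunique())


def test_cell_free_stage_rejects_with_cells_rows(scenarios):
    rows = [dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
                 compartment="medium", time_h=1.0, replicate=0, amount_nmol=1.0)]
    with pytest.raises(ValueError, match="cell_free"):
        KineticRateFitter(setup=SETUP, scenarios=scenarios, stage="cell_free").fit(make_dataset(rows))


def test_dataset_schema_validation():
    with pytest.raises(ValueError, match="missing columns"):
        KineticDataset(pd.DataFrame({"system": ["with_cells"]}))
    with pytest.raises(ValueError, match="cells"):
        make_dataset([dict(system="cell_free", scenario_label="a", nominal_uM=1.0,
                           compartment="cells", time_h=1.0, replicate=0, amount_nmol=1.0)])
    with pytest.raises(ValueError, match=">= 0"):
        make_dataset([dict(system="with_cells", scenario_label="a", nominal_uM=1.0,
                           compartment="cells", time_h=1.0, replicate=0, amount_nmol=-1.0)])


def test_unknown_fixed_rate_rejected(scenarios):
    fitter = KineticRateFitter(setup=SETUP, scenarios=scenarios, fixed={"bogus": 1.0})
    rows = [dict(system="with_cells", scenario_label="acute", nominal_uM=1.0,
                 compartment="medium", time_h=1.0, replicate=0, amount_nmol=1.0)]
    with pytest.raises(ValueError, match="bogus"):
        fitter.fit(make_dataset(rows))


def test_more_data_does_not_hurt_recovery(truth, scenarios):
    """Adding later noise-free sampling times can only sharpen the cell-free
    parameter estimates (monotone information)."""
    t = replace(truth, noise_cv_kinetics=0.0)
    errs = {}
    for times in [(1.0, 3.0, 6.0), (1.0, 3.0, 6.0, 24.0, 48.0, 168.0, 336.0)]:
        design = {"acute": (scenarios["acute"], times)}
        ds = generate_kinetics_dataset(t, design, with_cells=False, seed=0, setup=SETUP)
        res = fit_cell_free(ds, SETUP, scenarios, seed=0)
        errs[times] = max(
            abs(getattr(res.params, n) - getattr(truth.params, n)) / getattr(truth.params, n)
            for n in ("ka_plastic", "kd_plastic", "kdeg")
        )
    short, full = errs.keys()
    assert errs[full] <= errs[short] + 1e-6
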