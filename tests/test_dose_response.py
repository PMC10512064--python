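"""Viability normalisation, 4PL fitting, ICx inversion, re-expression."""

import numpy as np
import pandas as pd
import pytest

from invitrokin import (
    AssaySetup,
    FourPLFit,
    FourParamLogistic,
    compute_dose_metrics,
    compute_icx,
    fit_4pl,
    logistic4,
    normalize_viability,
    reexpress_dose_response,
    solve_piecewise_exact,
    standard_scenarios,
)

SETUP = AssaySetup()


def plate(label, rows):
    return pd.DataFrame(
        [dict(scenario_label=label, nominal_uM=n, replicate=r, fluorescence=f, role=role)
         for n, r, f, role in rows]
    )


class TestNormalization:
    def test_linear_interpolation_between_blank_and_control(self):
        raw = plate("24 h", [
            (0.0, 0, 100.0, "blank"),
            (0.0, 0, 1100.0, "control"),
            (5.0, 0, 600.0, "sample"),
        ])
        rec = normalize_viability(raw)
        sample = rec[rec["nominal_uM"] == 5.0]
        assert sample["percent_control"].iloc[0] == pytest.approx(50.0)

    def test_control_maps_to_100_and_blank_level_to_0(self):
        raw = plate("24 h", [
            (0.0, 0, 200.0, "blank"),
            (0.0, 0, 1200.0, "control"),
            (10.0, 0, 200.0, "sample"),
        ])
        rec = normalize_viability(raw)
        assert rec.loc[rec["nominal_uM"] == 0.0, "percent_control"].iloc[0] == pytest.approx(100.0)
        assert rec.loc[rec["nominal_uM"] == 10.0, "percent_control"].iloc[0] == pytest.approx(0.0)

    def test_dead_plate_rejected(self):
        raw = plate("24 h", [(0.0, 0, 500.0, "blank"), (0.0, 0, 400.0, "control")])
        with pytest.raises(ValueError, match="uninterpretable"):
            normalize_viability(raw)

    def test_missing_controls_rejected(self):
        raw = plate("24 h", [(5.0, 0, 600.0, "sample")])
        with pytest.raises(ValueError, match="blank and one control"):
            normalize_viability(raw)


class TestFourPL:
    @pytest.mark.parametrize("top,bottom,hill,ic50", [
        (100.0, 0.0, -1.5, 0.5),
        (100.0, 5.0, -4.0, 0.13),
        (95.0, 10.0, 2.0, 3.0),   # increasing curve, positive slope
    ])
    def test_exact_data_recovered_within_0p1_percent(self, top, bottom, hill, ic50):
        x = np.logspace(np.log10(ic50) - 1.5, np.log10(ic50) + 1.5, 8)
        y = logistic4(x, top, bottom, hill, np.log10(ic50))
        fit = fit_4pl(x, y)
        assert fit.top == pytest.approx(top, rel=1e-3)
        assert fit.bottom == pytest.approx(bottom, abs=1e-3 * (top - bottom))
        assert fit.hill_slope == pytest.approx(hill, rel=1e-3)
        assert fit.ic50 == pytest.approx(ic50, rel=1e-3)
        assert not fit.ambiguous
        # residuals vanish on exactly generated data
        est = FourParamLogistic().fit(x, y)
        assert np.sum((est.predict(x) - y) ** 2) <= 1e-12

    def test_flat_response_flagged_ambiguous_without_ci(self):
        x = np.logspace(-1, 1, 8)
        fit = fit_4pl(x, np.full(8, 100.0))
        assert fit.ambiguous
        assert fit.ci95 is None

    def test_constrained_asymptotes(self):
        x = np.logspace(-2, 1, 10)
        y = logistic4(x, 100.0, 0.0, -2.0, np.log10(0.8))
        fit = fit_4pl(x, y, constrain_top=100.0, constrain_bottom=0.0)
        assert fit.top == 100.0 and fit.bottom == 0.0
        assert fit.ic50 == pytest.approx(0.8, rel=1e-6)

    def test_midpoint_identity(self):
        fit = FourPLFit(top=100.0, bottom=0.0, hill_slope=-1.0, log_ic50=0.0, ic50=1.0, ci95=None)
        assert fit(1.0) == pytest.approx(50.0)

    def test_ci_covers_truth_on_noisy_data(self):
        rng = np.random.default_rng(11)
        x = np.repeat(np.logspace(-1.5, 1.5, 8), 3)
        y = logistic4(x, 100.0, 0.0, -1.5, 0.0) + rng.normal(0, 4.0, x.size)
        fit = fit_4pl(x, y)
        assert fit.ci95 is not None
        lo, hi = fit.ci95
        assert lo <= 1.0 <= hi
        assert lo <= fit.ic50 <= hi

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_4pl([1.0, 1.0, 2.0, 3.0], [90.0, 91.0, 50.0, 10.0])


class TestICx:
    FIT = FourPLFit(top=100.0, bottom=0.0, hill_slope=-1.0, log_ic50=0.0, ic50=1.0, ci95=None)

    def test_ic50_is_the_fixed_point(self):
        assert compute_icx(self.FIT, 50.0) == pytest.approx(1.0)

    def test_unit_slope_ic10_is_one_ninth_of_ic50(self):
        assert compute_icx(self.FIT, 10.0) == pytest.approx(1.0 / 9.0)

    def test_log_symmetry_around_ic50(self):
        d10 = np.log10(compute_icx(self.FIT, 10.0))
        d90 = np.log10(compute_icx(self.FIT, 90.0))
        assert d10 + d90 == pytest.approx(2 * self.FIT.log_ic50, abs=1e-12)

    def test_absolute_mode_matches_relative_for_full_span(self):
        # top=100, bottom=0: absolute (curve = 100 - x) and relative coincide
        rel = compute_icx(self.FIT, 20.0, mode="relative")
        ab = compute_icx(self.FIT, 20.0, mode="absolute")
        assert rel == pytest.approx(ab)

    def test_ambiguous_fit_rejected(self):
        bad = FourPLFit(top=100.0, bottom=0.0, hill_slope=-1.0, log_ic50=0.0,
                        ic50=1.0, ci95=None, ambiguous=True)
        with pytest.raises(ValueError, match="ambiguous"):
            compute_icx(bad, 50.0)

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError, match="strictly between"):
            compute_icx(self.FIT, 0.0)


def _true_metrics(truth, nominals):
    scenarios = standard_scenarios(1.0, SETUP)
    metrics = {}
    for label, tmpl in scenarios.items():
        for n in nominals:
            sc = tmpl.with_nominal(n, SETUP.medium_volume_ml)
            grid = np.arange(0.0, sc.end_time + 0.05, 0.25)
            traj = solve_piecewise_exact(truth.params, sc, grid)
            metrics[(label, n)] = compute_dose_metrics(traj, SETUP)
    return metrics


class TestReexpression:
    def test_nominal_metric_reproduces_plain_fits(self, truth):
        rng = np.random.default_rng(5)
        nominals = [0.625, 1.25, 2.5, 5.0, 10.0]
        rows = []
        for label in ("24 h", "7 d"):
            for n in nominals:
                for r in range(3):
                    rows.append(dict(scenario_label=label, nominal_uM=n, replicate=r,
                                     percent_control=float(logistic4(n, 100, 0, -2, np.log10(2.0))
                                                           + rng.normal(0, 3))))
        viab = pd.DataFrame(rows)
        metrics = _true_metrics(truth, nominals)
        fits_id, table_id = reexpress_dose_response(viab, metrics, "nominal")
        for label, grp in viab.groupby("scenario_label"):
            direct = fit_4pl(grp["nominal_uM"].to_numpy(), grp["percent_control"].to_numpy())
            assert fits_id[label].ic50 == pytest.approx(direct.ic50, rel=1e-9)

    def test_missing_metric_entry_is_named(self, truth):
        viab = pd.DataFrame([
            dict(scenario_label="24 h", nominal_uM=n, replicate=0,
                 percent_control=float(p))
            for n, p in [(0.5, 99), (1.0, 90), (2.0, 50), (4.0, 10), (8.0, 1)]
        ])
        with pytest.raises(ValueError, match="24 h.*0.5"):
            reexpress_dose_response(viab, {}, "cmax_cells")

    def test_cell_cmax_scale_collapses_scenarios(self, noisefree_truth):
        """Viability driven by cell-associated Cmax: on the cmax_cells scale
        the four scenarios' IC50s coincide, on the nominal scale the repeated
        scenarios look far more potent, and AUC-scale IC50s grow with
        exposure duration."""
        from invitrokin import generate_viability_dataset

        truth = noisefree_truth
        viab = generate_viability_dataset(truth, seed=0, setup=SETUP)
        nominals = [n for n in truth.viability_nominal_set if n > 0]
        metrics = _true_metrics(truth, nominals)

        _, t_cells = reexpress_dose_response(viab, metrics, "cmax_cells")
        ic = t_cells.set_index("scenario")["ic50"]
        assert ic.max() / ic.min() == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(ic, truth.viability_truth.ic50, rtol=0.05)

        _, t_nom = reexpress_dose_response(viab, metrics, "nominal")
        nom = t_nom.set_index("scenario")["ic50"]
        assert nom["24 h"] / nom["7 d"] >= 1.5

        for metric in ("auc_medium", "auc_cells"):
            _, t_auc = reexpress_dose_response(viab, metrics, metric)
            auc = t_auc.set_index("scenario")["ic50"]
            assert auc["24 h"] < auc["48 h"] < auc["7 d"] < auc["7 dW"]

    def test_metric_values_monotone_in_nominal(self, truth):
        """Linear kinetics: every dose metric is strictly increasing in the
        nominal concentration, so re-expression preserves dose ordering."""
        nominals = [0.625, 1.25, 2.5, 5.0]
        metrics = _true_metrics(truth, nominals)
        for label in ("24 h", "7 dW"):
            for attr in ("cmax_medium", "cmax_cells", "auc_medium", "auc_cells"):
                vals = [getattr(metrics[(label, n)], attr) for n in nominals]
                assert np.all(np.diff(vals) > 0)
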