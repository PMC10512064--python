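"""Viability normalisation and four-parameter logistic dose-response fits.

Resazurin fluorescence readings are background-subtracted and expressed as a
percentage of the vehicle-control cultures.  Concentration-effect curves use
the "log(inhibitor) vs. response - variable slope" four-parameter logistic:

    y(x) = bottom + (top - bottom) / (1 + 10**((log10(IC50) - log10(x)) * hill))

with the signed GraphPad convention: decreasing (inhibition) curves carry a
negative Hill slope.  The same curve can be fitted against any dose metric
(nominal concentration, Cmax or AUC in medium or cells), which is how the
dose-response is re-expressed on kinetics-derived dose scales.

Confidence intervals for log IC50 come from the asymptotic covariance of the
least-squares fit (t-based).  A fit is flagged *ambiguous* - and its CI
reported unavailable - when the covariance is singular or ill-conditioned,
when the log IC50 standard error spans more than the tested dose range, or
when the IC50 lands outside the tested range; this mirrors the "95% CI
cannot be calculated due to ambiguous curve fitting" behaviour of the cited
Prism procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .dosimetry import METRIC_NAMES, DoseMetrics

__all__ = [
    "FourPLFit",
    "FourParamLogistic",
    "logistic4",
    "normalize_viability",
    "fit_4pl",
    "compute_icx",
    "reexpress_dose_response",
]

VIABILITY_COLUMNS = ("scenario_label", "nominal_uM", "replicate", "percent_control")


def logistic4(x, top: float, bottom: float, hill_slope: float, log_ic50: float):
    """Evaluate the variable-slope 4PL; x = 0 maps to the zero-dose limit."""
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    zero = x <= 0
    # zero-dose limit: top for decreasing curves (hill < 0), bottom otherwise
    out[zero] = top if hill_slope < 0 else bottom
    with np.errstate(over="ignore"):
        q = 10.0 ** ((log_ic50 - np.log10(x[~zero])) * hill_slope)
    out[~zero] = bottom + (top - bottom) / (1.0 + q)
    return float(out[0]) if scalar else out


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic with IC50 and confidence status."""

    top: float
    bottom: float
    hill_slope: float
    log_ic50: float
    ic50: float
    ci95: tuple[float, float] | None
    dose_metric: str = "nominal"
    ambiguous: bool = False
    se_log_ic50: float | None = None
    n_obs: int = 0
    note: str = ""

    def __call__(self, x):
        return logistic4(x, self.top, self.bottom, self.hill_slope, self.log_ic50)


def normalize_viability(raw: pd.DataFrame) -> pd.DataFrame:
    """Express raw fluorescence as % of vehicle-control cultures.

    ``raw`` needs columns ``scenario_label, nominal_uM, replicate,
    fluorescence, role`` with role in {"blank", "control", "sample"}; blanks
    are resazurin-solution-only wells, controls the vehicle (0 µM) cultures.
    Per scenario:

        percent_control = 100 * (raw - mean blank) / (mean control - mean blank)

    Blank rows are consumed; control and sample rows come back as viability
    records.
    """
    needed = {"scenario_label", "nominal_uM", "replicate", "fluorescence", "role"}
    missing = needed - set(raw.columns)
    if missing:
        raise ValueError(f"plate table is missing columns: {sorted(missing)}")
    records = []
    for label, plate in raw.groupby("scenario_label", sort=False):
        blanks = plate.loc[plate["role"] == "blank", "fluorescence"]
        controls = plate.loc[plate["role"] == "control", "fluorescence"]
        if blanks.empty or controls.empty:
            raise ValueError(f"scenario {label!r} needs at least one blank and one control well")
        b, c = blanks.mean(), controls.mean()
        if c <= b:
            raise ValueError(
                f"scenario {label!r}: control signal ({c:.4g}) does not exceed blank ({b:.4g}); "
                "plate is uninterpretable"
            )
        keep = plate[plate["role"].isin(["control", "sample"])]
        records.append(
            pd.DataFrame(
                {
                    "scenario_label": label,
                    "nominal_uM": keep["nominal_uM"].to_numpy(),
                    "replicate": keep["replicate"].to_numpy(),
                    "percent_control": 100.0 * (keep["fluorescence"].to_numpy() - b) / (c - b),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Least-squares 4PL fit against a chosen dose metric.

    Parameters
    ----------
    constrain_top, constrain_bottom : float, optional
        Pin the corresponding asymptote (unconstrained by default, matching
        the cited Prism procedure).
    max_condition : float
        Condition-number threshold on the parameter covariance above which
        the fit is flagged ambiguous.
    dose_metric : str
        Name of the dose scale the x values live on (bookkeeping only).

    Attributes (after ``fit``)
    --------------------------
    top_, bottom_, hill_slope_, log_ic50_, ic50_ : float
    ci95_ : (low, high) or None
    ambiguous_ : bool
    result_ : FourPLFit
    """

    def __init__(
        self,
        constrain_top: float | None = None,
        constrain_bottom: float | None = None,
        max_condition: float = 1e8,
        dose_metric: str = "nominal",
    ):
        self.constrain_top = constrain_top
        self.constrain_bottom = constrain_bottom
        self.max_condition = max_condition
        self.dose_metric = dose_metric

    # parameter packing: free parameters in the order top, bottom, hill, logIC50
    def _pack_model(self):
        fixed_top, fixed_bot = self.constrain_top, self.constrain_bottom

        def model(x, *theta):
            it = iter(theta)
            top = fixed_top if fixed_top is not None else next(it)
            bottom = fixed_bot if fixed_bot is not None else next(it)
            hill, lic50 = next(it), next(it)
            return logistic4(x, top, bottom, hill, lic50)

        n_free = 2 + (fixed_top is None) + (fixed_bot is None)
        return model, n_free

    def fit(self, x, y) -> "FourParamLogistic":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same shape")
        if not np.all(np.isfinite(y)):
            raise ValueError("y values must be finite")
        pos = x > 0
        x, y = x[pos], y[pos]
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct positive dose values")

        lx = np.log10(x)
        order = np.argsort(lx)
        y_low = float(np.mean(y[order][: max(2, len(y) // 4)]))
        y_high = float(np.mean(y[order][-max(2, len(y) // 4):]))
        top0 = self.constrain_top if self.constrain_top is not None else max(y_low, y_high)
        bot0 = self.constrain_bottom if self.constrain_bottom is not None else min(y_low, y_high)
        sign = -1.0 if y_low >= y_high else 1.0  # decreasing response -> negative slope
        mid = 0.5 * (top0 + bot0)
        lic0 = float(lx[np.argmin(np.abs(y - mid))])

        model, n_free = self._pack_model()
        best = None
        for mag in (0.5, 1.0, 2.0, 4.0):
            p0 = []
            if self.constrain_top is None:
                p0.append(top0)
            if self.constrain_bottom is None:
                p0.append(bot0)
            p0 += [sign * mag, lic0]
            try:
                with warnings.catch_warnings():
                    # a singular covariance is handled below via the ambiguous flag
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
            except RuntimeError:
                continue
            ssr = float(np.sum((model(x, *popt) - y) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise RuntimeError("4PL fit failed to converge from all starting points")

        ssr, popt, pcov = best
        it = iter(popt)
        top = self.constrain_top if self.constrain_top is not None else float(next(it))
        bottom = self.constrain_bottom if self.constrain_bottom is not None else float(next(it))
        hill, lic50 = float(next(it)), float(next(it))

        lx_range = (float(lx.min()), float(lx.max()))
        note = ""
        ambiguous = False
        se = None
        ci = None
        cov_ok = np.all(np.isfinite(pcov))
        if cov_ok and np.linalg.cond(pcov) > self.max_condition:
            cov_ok = False
            note = "ill-conditioned parameter covariance"
        if not cov_ok:
            ambiguous = True
            note = note or "parameter covariance could not be estimated"
        else:
            se = float(np.sqrt(pcov[len(popt) - 1, len(popt) - 1]))
            if se > (lx_range[1] - lx_range[0]):
                ambiguous = True
                note = "log IC50 standard error spans more than the tested dose range"
            else:
                dof = max(len(y) - n_free, 1)
                tval = float(stats.t.ppf(0.975, dof))
                ci = (10.0 ** (lic50 - tval * se), 10.0 ** (lic50 + tval * se))
        if not (lx_range[0] <= lic50 <= lx_range[1]):
            ci = None
            note = (note + "; " if note else "") + "IC50 outside the tested dose range"

        self.top_, self.bottom_ = top, bottom
        self.hill_slope_, self.log_ic50_ = hill, lic50
        self.ic50_ = 10.0 ** lic50
        self.ci95_ = ci
        self.ambiguous_ = ambiguous
        self.result_ = FourPLFit(
            top=top,
            bottom=bottom,
            hill_slope=hill,
            log_ic50=lic50,
            ic50=self.ic50_,
            ci95=ci,
            dose_metric=self.dose_metric,
            ambiguous=ambiguous,
            se_log_ic50=se,
            n_obs=len(y),
            note=note,
        )
        return self

    def predict(self, x):
        return logistic4(x, self.top_, self.bottom_, self.hill_slope_, self.log_ic50_)


def fit_4pl(x, y, **kw) -> FourPLFit:
    """Functional wrapper around :class:`FourParamLogistic`."""
    return FourParamLogistic(**kw).fit(x, y).result_


def compute_icx(fit: FourPLFit, x_percent: float, mode: str = "relative") -> float:
    """Invert the fitted 4PL for the dose giving x% effect.

    ``relative`` (default) returns the dose where the curve equals
    ``top - (x_percent/100) * (top - bottom)``; ``absolute`` the dose where
    the curve equals ``100 - x_percent`` on the percent-of-control scale.
    """
    if not (0 < x_percent < 100):
        raise ValueError("x_percent must lie strictly between 0 and 100")
    if fit.ambiguous:
        raise ValueError("cannot derive ICx from an ambiguous fit")
    if fit.hill_slope == 0:
        raise ValueError("flat curve (hill slope 0) has no ICx")
    if mode == "relative":
        f = x_percent / 100.0
        return 10.0 ** (fit.log_ic50 - np.log10(f / (1.0 - f)) / fit.hill_slope)
    if mode == "absolute":
        target = 100.0 - x_percent
        span = fit.top - fit.bottom
        q = span / (target - fit.bottom) - 1.0
        if not np.isfinite(q) or q <= 0:
            raise ValueError(
                f"absolute response target {target}% is outside the fitted curve's range"
            )
        return 10.0 ** (fit.log_ic50 - np.log10(q) / fit.hill_slope)
    raise ValueError(f"unknown ICx mode {mode!r}")


def reexpress_dose_response(
    viability: pd.DataFrame,
    metrics: Mapping[tuple[str, float], DoseMetrics],
    metric_name: str,
    **fit_kw,
) -> tuple[dict[str, FourPLFit], pd.DataFrame]:
    """Fit per-scenario 4PL curves on a kinetics-derived dose scale.

    ``viability`` holds normalised records (scenario_label, nominal_uM,
    replicate, percent_control); ``metrics`` maps (scenario_label, nominal)
    to the :class:`DoseMetrics` of that exposure.  ``metric_name`` selects
    the x axis: ``nominal`` keeps the nominal concentration, the others
    substitute the corresponding kinetics-derived metric.  Zero-dose records
    are excluded from the fits (no position on a log dose axis).

    Returns the per-scenario fits and a combined IC50 summary table.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"metric_name must be one of {METRIC_NAMES}, got {metric_name!r}")
    missing = set(viability.columns).symmetric_difference(VIABILITY_COLUMNS) & set(VIABILITY_COLUMNS)
    if missing - set(viability.columns):
        raise ValueError(f"viability table is missing columns: {sorted(missing)}")

    def metric_value(label: str, nominal: float) -> float:
        if metric_name == "nominal":
            return nominal
        key = (label, nominal)
        if key not in metrics:
            raise ValueError(f"no dose metrics for scenario {label!r} at {nominal} µM")
        return getattr(metrics[key], metric_name)

    fits: dict[str, FourPLFit] = {}
    rows = []
    for label, grp in viability.groupby("scenario_label", sort=False):
        grp = grp[grp["nominal_uM"] > 0]
        x = np.array([metric_value(label, n) for n in grp["nominal_uM"]])
        fit = fit_4pl(x, grp["percent_control"].to_numpy(), dose_metric=metric_name, **fit_kw)
        fits[label] = fit
        ci = fit.ci95 or (np.nan, np.nan)
        rows.append(
            {
                "metric": metric_name,
                "scenario": label,
                "ic50": fit.ic50,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "hill_slope": fit.hill_slope,
                "ambiguous": fit.ambiguous,
                "note": fit.note,
            }
        )
    return fits, pd.DataFrame(rows)
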