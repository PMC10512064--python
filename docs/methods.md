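# Methods

## Compartment model

The well is described by three well-mixed pools holding amounts (nmol) of
the test chemical: the exposure medium, the cells, and the well plastic.
All transfers are first order in the source pool, and an irreversible
first-order loss (`kdeg`, interpreted as abiotic degradation) acts on the
medium only.  The model is linear between dosing events, which has two
consequences used throughout the package: trajectories scale exactly with
the dose, so one rate set serves all nominal concentrations; and the exact
solution is a piecewise matrix exponential, which doubles as the correctness
oracle for the numerical integrator and as the fast path inside the
calibration loop.

A medium change is modelled as a complete, instantaneous exchange: the
medium amount jumps to the fresh dose (zero during washout) while the cell
and plastic amounts are continuous across the event.  The trajectory grid
stamps each event time twice (pre- and post-event state), which makes the
discontinuity bookkeeping lossless: trapezoid integration sees a zero-width
panel at the jump, maxima see both sides, and the mass-balance ledger
(dosed = in-system + degraded + discarded) closes to ~1e−14 relative.

The dosing schedule is configurable; the default mirrors a
three-medium-changes-per-week culture: doses at 0, 48 and 120 h, washout
refreshes with blank medium at 168, 216 and 288 h, collections at 24, 48,
168 (`7 d`) and 336 h (`7 dW`).  The clock times are a choice (only the
frequency is fixed by the design being emulated); they can be overridden in
the scenario specification.

Deliberately out of scope: no headspace/evaporation pool, no serum-binding
sub-compartment, no metabolite tracking, and no estimation of the free
(unbound) medium concentration — dose metrics are built from nominal-scale
amounts.

## Numerical choices

* `simulate_scenario` integrates each inter-event segment with DOP853 at
  rtol 1e−10 / atol 1e−13; agreement with the matrix-exponential oracle is
  ~1e−10 relative, far inside the 1e−6 test tolerance.
* Default grid resolution 0.1 h; refining tenfold moves AUCs by ~1e−5
  relative, so trapezoid error is negligible against every tolerance used.
* Tiny negative amounts from solver round-off (~−1e−15) are clipped to zero.
* The lean calibration path propagates states sequentially with one cached
  matrix exponential per distinct step size.

## Calibration

The objective is a sum of squared *relative* residuals, each time point
down-weighted by the number of observations sharing it
(`w = 1/n(t)`), so the dense day-one sampling and the sparse late
collections contribute equal total weight per time point, across nominal
concentrations, compartments and replicates.  Observations below a
quantification floor of 1e−3 nmol are excluded: relative error is unstable
near zero.

Optimisation is BFGS on log-transformed rates — positivity by
parameterisation rather than penalties — with 8 starts drawn log-uniformly
from [1e−4, 1] /h by a seeded generator.  A start counts as converged if
BFGS reports success or terminates with a numerically negligible gradient
(finite-difference gradients on noisy objectives routinely trip the
"precision loss" status at a perfectly good optimum).  Identical data, seed
and starts give bitwise-identical results.

Fitting is two-stage by default: the cell-free system (medium + plastic)
determines `ka_plastic`, `kd_plastic` and `kdeg`; the with-cells system then
determines `ka_cell`, `kd_cell` and (re-fitted) plastic rates with `kdeg`
pinned.  A config switch (`fix_plastic`) pins the plastic rates too, and
the inclusion filter can restrict the with-cells stage to a time window or a
subset of nominal concentrations — the holdout-prediction study uses the
first 24 h of the 1 µM data only.

No identifiability analysis (profile likelihood) and no Bayesian posterior
are attempted; confidence in the rates is assessed operationally, through
holdout fold errors.

## Dose metrics

Over a window [0, T]: `cmax_medium` is the peak medium amount divided by the
medium volume (nmol/mL ≡ µM); `cmax_cells` the peak cell-associated amount
per 100,000 cells (division by 20 at the default 2×10⁶ cells/well);
`auc_medium`/`auc_cells` trapezoid integrals of the *amount* series
(nmol·h), not of concentrations.  The window of each scenario spans its full
collection horizon, so the washout scenario integrates over all 336 h.  The
cell number is held at its seeded value even at cytotoxic doses; the
resulting bias in per-cell normalisation at high doses is accepted as part
of the metric's definition, not corrected.

## Dose–response

The four-parameter logistic uses the signed variable-slope convention
(decreasing curves have negative Hill slope), unconstrained asymptotes by
default, optional top/bottom constraints.  Initialisation reads the
asymptotes and midpoint off the sorted data and tries four Hill-slope
magnitudes; the best least-squares fit wins, deterministically.  The 95% CI
of log IC50 is t-based from the asymptotic covariance.  A fit is flagged
*ambiguous* when the covariance is missing or has condition number above
1e8, or when the log-IC50 standard error exceeds the tested dose range; the
CI is additionally withheld when the IC50 lies outside the tested range.
ICx is the closed-form inversion at `top − (x/100)(top − bottom)`
(relative mode, default) or at `100 − x` percent-of-control (absolute mode)
— both are provided because either reading is defensible.

## Synthetic data generator

The generator emulates the measurement structure the analysis assumes:
destructive sampling (each time point an independent well) at 1, 3, 6, 24,
48, 168 and 336 h; 1–2 µM nominal kinetic concentrations in triplicate;
a separate cell-free arm; a viability panel at 0.625–15 µM.  Kinetic noise
is multiplicative lognormal with mean one and CV 15% (a typical HPLC-UV
replicate spread; the emulated data report only SD bars, so this is a
placeholder exposed in the config).  Viability noise is additive Gaussian
with SD 8 percentage points, truncated to [−5, 120]%; six replicates per
condition (the emulated design used 3–9).  Viability responses are computed
from the *cell-associated Cmax* through a steep logistic (Hill slope −4,
IC50 0.13 nmol per 100,000 cells, top 100, bottom 0) — the generator embeds
the hypothesis that cell-associated peak exposure drives cytotoxicity, which
is exactly what makes it a fair test bed for the dose-metric invariance
analysis.

The default rate constants (`ka_cell` 0.163, `kd_cell` 0.144, `ka_plastic`
0.552, `kd_plastic` 2.0, `kdeg` 0.0043 /h) were calibrated once by
differential evolution (`scripts/calibrate_ground_truth.py`, seeded,
deterministic) against printed single-dose anchors: ~12% of the dose in
cells at 1 h, ~45% at 24 h, plastic ahead of cells at 1 h, near-complete
recovery through 24 h, and 10–15% degraded by 48 h.  One anchor cannot be
met jointly with the others in this model family: degradation loss grows
with the time-integral of the medium amount, which is front-loaded, so the
loss accrued between 24 and 48 h can never exceed the loss accrued before
24 h — recovery ≥95% at 24 h therefore forces recovery ≳91% at 48 h, just
above the 85±5% band.  The calibration prioritises the day-one anchors and
lands at 95.3% / 91.3%; the corresponding acceptance check is left failing
rather than loosened, since the gap is structural.

What passing tests on generated data do **not** show: the generator is
noise-faithful in structure, not in magnitude (real replicate spread,
plate-position effects, inter-experiment variance and cytotoxicity-induced
cell-number changes are absent), and its viability mechanism is the
clean single-metric hypothesis — real data can only approximate the
dose-metric collapse the synthetic study reproduces.

## Problem sizes

The holdout-prediction study (`invitrokin.validation`) runs 20 repetitions
of dataset generation plus two-stage calibration (8 BFGS starts per stage)
and scores 48 held-out observations per repetition (960 in total); it
completes in well under a minute on one core.  The CI-coverage check fits
200 noisy curves with triplicates at 8 doses.  These sizes were chosen to
make the checks statistically meaningful while keeping the whole suite fast
enough to run habitually.
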