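#!/usr/bin/env python
"""Calibrate the synthetic generator's default rate constants.

Finds first-order rate constants whose 1 µM single-dose kinetics reproduce
the study's printed anchors:

  * ~12% of the dosed mass in cells after 1 h and ~45% after 24 h,
  * plastic binding faster than cell uptake (plastic > cells at 1 h),
  * near-complete recovery through 24 h,
  * roughly 85-90% recovery at 48 h (10-15% degraded).

The early-recovery and 48 h-recovery anchors pull against each other under
first-order degradation of the medium: degradation loss accrues with the
time-integral of the medium amount, which is largest on day one, so the loss
between 24 and 48 h can never exceed the loss accrued before 24 h.  The
objective therefore applies a hard hinge on recovery(24 h) >= 95.3% and a
soft target of 89% at 48 h; the optimum lands at ~91% recovery at 48 h,
which is as close to the 48 h anchor as the model family can get.

The printed optimum is frozen into ``invitrokin.synthetic._DEFAULT_RATES``.
Run time is a few minutes (differential evolution, seed 1, deterministic).
"""

import numpy as np
from scipy.linalg import expm
from scipy.optimize import differential_evolution

from invitrokin import RateParameters, repeated_scenario, solve_piecewise_exact


def single_dose_state(x: np.ndarray, t: float) -> np.ndarray:
    """[medium, cells, plastic] fractions of a unit dose at time t."""
    params = RateParameters.from_array(x)
    return expm(params.system_matrix() * t) @ np.array([1.0, 0.0, 0.0])


def anchors(x: np.ndarray) -> dict:
    s1 = single_dose_state(x, 1.0)
    s24 = single_dose_state(x, 24.0)
    s48 = single_dose_state(x, 48.0)
    return {
        "cell_fraction_1h": s1[1],
        "plastic_fraction_1h": s1[2],
        "cell_fraction_24h": s24[1],
        "recovery_24h": s24.sum(),
        "recovery_48h": s48.sum(),
    }


def loss(log_x: np.ndarray) -> float:
    a = anchors(np.exp(log_x))
    r = 0.0
    r += ((a["cell_fraction_1h"] - 0.12) / 0.01) ** 2
    r += ((a["cell_fraction_24h"] - 0.45) / 0.01) ** 2
    r += (min(0.0, a["recovery_24h"] - 0.953) / 0.001) ** 2  # hard floor ~95%
    r += ((a["recovery_48h"] - 0.89) / 0.01) ** 2
    # plastic sorption faster than cell uptake, but plastic stays a minority pool
    r += (min(0.0, a["plastic_fraction_1h"] - 1.5 * a["cell_fraction_1h"]) / 0.01) ** 2
    r += (max(0.0, a["plastic_fraction_1h"] - 0.45) / 0.02) ** 2
    return r


def main() -> None:
    bounds = [(np.log(1e-4), np.log(2.0))] * 4 + [(np.log(1e-5), np.log(0.05))]
    result = differential_evolution(
        loss, bounds, seed=1, maxiter=800, tol=1e-12, popsize=40, polish=True
    )
    x = np.exp(result.x)
    params = RateParameters.from_array(x)
    print("calibrated rate constants (1/h):")
    for name in RateParameters._NAMES:
        print(f"  {name:12s} = {getattr(params, name):.8f}")
    print("\nanchors at the optimum (fractions of a 1 µM dose):")
    for key, value in anchors(x).items():
        print(f"  {key:22s} = {value:.4f}")
    traj = solve_piecewise_exact(params, repeated_scenario(1.0), [168.0])
    total = traj.total_in_system()[-1]
    print(f"\nrepeated dosing: total in system at 168 h = {total:.3f} nmol (single dose = 2)")


if __name__ == "__main__":
    main()
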