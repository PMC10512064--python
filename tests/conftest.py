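from dataclasses import replace

import pytest

from invitrokin import AssaySetup, default_ground_truth
from invitrokin.kinetics import acute_scenario, repeated_scenario, washout_scenario


@pytest.fixture(scope="session")
def setup():
    return AssaySetup()


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def noisefree_truth(truth):
    return replace(truth, noise_cv_kinetics=0.0, noise_sd_viability=0.0)


@pytest.fixture(scope="session")
def study_scenarios(setup):
    """Scenario templates (at 1 µM) covering the kinetic study arms."""
    return {
        "acute": acute_scenario(1.0, 336.0, setup, label="acute"),
        "7 d": repeated_scenario(1.0, setup),
        "7 dW": washout_scenario(1.0, setup),
    }
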