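import numpy as np
import pytest

from psmsim import ScenarioConfig, calibrate_parameters, generate_cohort

# moderate calibration draw for unit tests; the acceptance tests use the
# full-size draw
UNIT_N_CAL = 400_000


@pytest.fixture(scope="session")
def weak05_logistic():
    """Calibrated weak-assignment, 50% treated, logistic-outcome scenario (n=1000)."""
    cfg = ScenarioConfig("weak", 0.5, 1000, "logistic")
    return calibrate_parameters(cfg, n_cal=UNIT_N_CAL)


@pytest.fixture(scope="session")
def weak05_linear():
    """Calibrated linear-probability counterpart of the primary test scenario."""
    cfg = ScenarioConfig("weak", 0.5, 1000, "linear_probability")
    return calibrate_parameters(cfg, n_cal=UNIT_N_CAL)


@pytest.fixture(scope="session")
def cohort(weak05_logistic):
    return generate_cohort(weak05_logistic, seed=20_240_001)


@pytest.fixture()
def rng():
    return np.random.default_rng(991)
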