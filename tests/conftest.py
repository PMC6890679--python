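import numpy as np
import pytest

import allergenrisk as ar

# peanut-in-cereal-bars ground truth used across the suite
WEIBULL_TRUTH = (0.38, 229.6)
LOGNORMAL_Z_TRUTH = (4.09, 2.98)
CONSUMPTION_TRUTH = (-3.719, 0.747)


@pytest.fixture(scope="session")
def weibull_records():
    """158 synthetic DBPCFC outcomes from the Weibull threshold truth."""
    return ar.generate_challenge_data(
        "weibull", WEIBULL_TRUTH, 158, seed=20240
    )


@pytest.fixture(scope="session")
def lognormal_records():
    """158 synthetic DBPCFC outcomes from the lognormal threshold truth."""
    return ar.generate_challenge_data(
        "lognormal", LOGNORMAL_Z_TRUTH, 158, seed=20241
    )


@pytest.fixture(scope="session")
def concentration_sample():
    """24 exponential concentrations at the fitted rate 0.013/ppm."""
    return ar.generate_concentration("exponential", (0.013,), 24, seed=20242)


@pytest.fixture(scope="session")
def consumption_sample():
    """350 lognormal single-occasion amounts (kg)."""
    return ar.generate_consumption(CONSUMPTION_TRUTH, 350, seed=20243)
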