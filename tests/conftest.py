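import numpy as np
import pytest

from cav3sim import CAV33_REST, CAV33_SHIFTED, cav33_model
from cav3sim.ca_dynamics import calibrate
from cav3sim.synthetic import DEFAULT_ATTENUATION_ALPHA, SyntheticConfig


@pytest.fixture(scope="session")
def rest():
    return CAV33_REST


@pytest.fixture(scope="session")
def shifted():
    return CAV33_SHIFTED


@pytest.fixture(scope="session")
def model():
    return cav33_model("rest")


@pytest.fixture(scope="session")
def clean_config():
    """Single noiseless cell without variability, coarse but converged dt."""
    return SyntheticConfig(n_cells=1, noise_sd=0.0, g_max_cv=0.0,
                           v_half_jitter_sd=0.0, sample_dt=0.2)


@pytest.fixture(scope="session")
def calibrated_rates():
    """(k_on, k_off) fitted to the 18 s onset / 20 s recovery half-times."""
    return calibrate(attenuation_alpha=DEFAULT_ATTENUATION_ALPHA, sample_dt=0.2)


@pytest.fixture(scope="session")
def v_grid():
    return np.arange(-130.0, 40.1, 1.0)
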