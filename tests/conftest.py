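import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcdm.synthetic import simulate_mcg, simulate_system

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lorenz_series():
    """Lorenz x-coordinate in the standard chaotic regime, 20k samples."""
    return simulate_system("lorenz", n_samples=20000)


@pytest.fixture(scope="session")
def logistic_series():
    """Fully chaotic logistic map orbit (r = 4), 5k samples."""
    return simulate_system("logistic", n_samples=5000)


@pytest.fixture(scope="session")
def sine_series():
    """Noiseless sine, incommensurate with the sampling grid (9.7 Hz at
    1 kHz) so phase-space neighbors are genuine points on the curve."""
    return simulate_system("sine", {"frequency": 9.7, "sampling_rate": 1000.0}, 3000)


@pytest.fixture(scope="session")
def period100_sine():
    """Sine with an exact 100-sample period, for the delay criterion."""
    return simulate_system("sine", {"frequency": 10.0, "sampling_rate": 1000.0}, 3000)


@pytest.fixture(scope="session")
def healthy_record():
    return simulate_mcg("healthy", n_cycles=10, seed=3, subject_id="H0001")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
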