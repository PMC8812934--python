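import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluorotax.calibration import published_calibration
from fluorotax.chemotax import load_default_ratio_matrix
from fluorotax.simulate import SimulationConfig, simulate_reference_db

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ratios():
    return load_default_ratio_matrix()


@pytest.fixture(scope="session")
def published_model():
    return published_calibration()


@pytest.fixture(scope="session")
def small_db():
    """Synthetic reference database of 60 samples over 4 areas."""
    db, truth = simulate_reference_db(SimulationConfig(n_samples=60, seed=3))
    return db, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
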