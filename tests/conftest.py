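import numpy as np
import pytest
from hypothesis import settings

from nirselect.synthetic import SynthConfig, generate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """120 x 150 synthetic spectra with default five-region truth."""
    return generate(SynthConfig(n_samples=120, n_channels=150, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def linear_problem(rng):
    """Well-conditioned full-rank regression problem (30 x 6)."""
    X = rng.normal(size=(30, 6))
    beta = np.array([1.5, -2.0, 0.0, 0.7, 3.0, -1.2])
    y = X @ beta + 0.05 * rng.normal(size=30)
    return X, y
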