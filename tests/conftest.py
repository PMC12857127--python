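import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dtmarkov import Observation, ObservationSet, TransitionStructure


@pytest.fixture
def star3():
    """Three-state star: transient state 1, absorbing states 2 and 3."""
    return TransitionStructure.star((1, 2, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(star3, rng):
    """A hand-mixed dataset of exact, censored, and interval records."""
    obs = [
        Observation("a", 0, 1, 1, "exact", 2, covariates=[0.2, 0.8]),
        Observation("b", 0, 0, None, "exact", 3, covariates=[0.5, 0.5]),
        Observation("c", 0, 1, 2, "interval", None, 1, 3, covariates=[0.9, 0.1]),
        Observation("d", 0, 1, 1, "interval", None, 0, 2, covariates=[0.4, 0.6]),
        Observation("e", 0, 0, None, "exact", 0, covariates=[0.1, 0.9]),
    ]
    return ObservationSet(obs, star3)
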