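import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cohortcea import ModelSpec, StructuralVariant, TransitionProfile, default_config
from cohortcea.synthetic import known_answer_cases

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

VARIANTS = list(StructuralVariant)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def brv_profile(config):
    return config.transition_profile("BRV")


@pytest.fixture(scope="session")
def cases():
    return known_answer_cases()


@pytest.fixture
def spec():
    return ModelSpec()


def random_profile(rng: np.random.Generator, concentration: float = 5.0) -> TransitionProfile:
    """A random simplex-valued transition profile (no SEs)."""
    p = rng.dirichlet(np.full(4, concentration))
    return TransitionProfile("RND", *map(float, p))
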