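import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssrsa.core import ConditionSet, correlation_distance_rdm
from ssrsa.synthetic import make_mesh

settings.register_profile(
    "ssrsa",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ssrsa")


@pytest.fixture(scope="session")
def small_mesh():
    """Two 30-vertex hemispheres, 50 mm radius."""
    return make_mesh(30, 50.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_rdm(rng, n=5, conditions=None, n_features=12):
    """A valid random RDM built from random condition responses."""
    responses = rng.normal(size=(n, n_features))
    return correlation_distance_rdm(responses, conditions)


@pytest.fixture
def conditions4():
    return ConditionSet(("a", "b", "c", "d"), (300.0, 310.0, 320.0, 330.0))
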