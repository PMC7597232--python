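import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dicelattice as dl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def angled():
    return dl.builtin_molecule("angled", 1)


@pytest.fixture(scope="session")
def stretched():
    return dl.builtin_molecule("stretched", 1)


@pytest.fixture(scope="session")
def inert():
    return dl.builtin_molecule("inert", 2)


@pytest.fixture(scope="session")
def angled_inert_space(angled, inert):
    return dl.StateSpace((angled, inert))


@pytest.fixture(scope="session")
def sphere_specs():
    """Two uniform 'sphere' molecules carrying classes 1 and 2."""
    from dicelattice.molecules import uniform_molecule

    return uniform_molecule(1, 1), uniform_molecule(2, 2)


@pytest.fixture(scope="session")
def sphere_space(sphere_specs):
    return dl.StateSpace(sphere_specs, sphere=True)


def random_distribution(n: int, rng: np.random.Generator) -> dl.ClusterDistribution:
    """A random valid distribution over an n-state-per-position cluster."""
    p = rng.dirichlet(np.ones(n**4)).reshape(n, n, n, n)
    return dl.ClusterDistribution(p)
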