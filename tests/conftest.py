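import numpy as np
import pytest
from hypothesis import settings

import cmemor as cm

settings.register_profile("deterministic", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def birth_death():
    return cm.build_birth_death(k=10.0, gamma=1.0, bound=60)


@pytest.fixture(scope="session")
def small_switch():
    """Mini follicle switch on a 31x31 lattice for fast operator checks."""
    return cm.build_switch(bound=30, final_time=1e5)


def random_generator_matrix(rng, d):
    """Random sink-type FSP-like generator: nonnegative off-diagonals,
    column sums <= 0."""
    A = rng.random((d, d)) * (rng.random((d, d)) < 0.5)
    np.fill_diagonal(A, 0.0)
    leak = rng.random(d) * 0.1
    np.fill_diagonal(A, -(A.sum(axis=0) + leak))
    return A
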