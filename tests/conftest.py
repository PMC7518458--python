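import numpy as np
import pytest

from einscale import (TransitionStructure, cardiac_fixture,
                      expand_state_space, normalize)
from einscale.generators import two_block_noisy


def random_transition_structure(rng: np.random.Generator,
                                n: int) -> TransitionStructure:
    """A dense random row-stochastic structure (Dirichlet rows)."""
    M = rng.dirichlet(np.ones(n), size=n)
    return TransitionStructure([f"n{i}" for i in range(n)], M)


@pytest.fixture(scope="session")
def cardiac_stg():
    return expand_state_space(cardiac_fixture())


@pytest.fixture(scope="session")
def cardiac_ts(cardiac_stg):
    return cardiac_stg.transition_structure()


@pytest.fixture(scope="session")
def two_block_ts():
    return normalize(two_block_noisy(6, block_sizes=(4, 2)))
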