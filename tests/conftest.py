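import numpy as np
import pytest

from cropweed import synthetic as syn


@pytest.fixture(scope="session")
def species():
    return syn.default_species()


@pytest.fixture(scope="session")
def small_bench():
    """A small side-32 RGB benchmark: 20/class train, 10/class test."""
    return syn.build_benchmark((20,) * 6, (10,) * 6, modality="rgb", side=32, seed=0)


@pytest.fixture(scope="session")
def fitness_bench():
    """The optimization-time sample sizes: 50/class train, 10/class test."""
    return syn.build_benchmark((50,) * 6, (10,) * 6, modality="rgb", side=32, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
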