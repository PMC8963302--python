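import numpy as np
import pytest

import cdrloop as cl
from cdrloop.features import AMINO_ALPHABET


@pytest.fixture(scope="session")
def toy_pair():
    """One (model, reference) toy antibody pair at sigma = 1.0."""
    return cl.make_toy_antibody(cl.FixtureSpec(sigma=1.0, seed=7))


@pytest.fixture(scope="session")
def reference(toy_pair):
    return toy_pair[1]


@pytest.fixture(scope="session")
def model(toy_pair):
    return toy_pair[0]


@pytest.fixture(scope="session")
def ref_loops(reference):
    return cl.extract_loops(reference)


@pytest.fixture(scope="session")
def small_cfg():
    """Small network configuration used throughout the unit tests."""
    return cl.EGNNConfig(hidden_width=16, message_width=8, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_cfg):
    return cl.init_ensemble(small_cfg)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ALPHABET[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="session")
def rand_seq():
    """Callable fixture: draw a random loop sequence from a generator."""
    return random_sequence
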