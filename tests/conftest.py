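import numpy as np
import pytest

from hybridtest.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A 20-locus scenario small enough for per-test use."""
    return SimulationConfig(n_loci=20, seed=7)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
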