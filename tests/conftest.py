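import numpy as np
import pytest

import rotasub as rs
from rotasub import fixtures as fx


@pytest.fixture(scope="session")
def alpha55():
    return rs.build_alphabet()


@pytest.fixture(scope="session")
def toy9():
    """Random reversible 9-state toy model (+ lumped 4-group counterpart)."""
    fine, coarse, counts = fx.toy_model(seed=2)
    return fine, coarse, counts


@pytest.fixture(scope="session")
def model55(alpha55):
    """A random superscaled 55-state fixture model."""
    return rs.model_from_counts(fx.toy_counts(alpha55, seed=1), alpha55,
                                name="fixture55")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
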