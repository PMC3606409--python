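import numpy as np
import pytest

from stepgls import ARModel, simulate_ar


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def ar1_long():
    """A long AR(1) realization with a = 0.5, unit innovation SD."""
    model = ARModel(order=1, coefficients=(0.5,), innovation_sd=1.0)
    return model, simulate_ar(model, 200_000, seed=11)


@pytest.fixture(scope="session")
def white_long():
    return np.random.default_rng(7).normal(size=100_000)
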