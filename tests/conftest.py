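import numpy as np
import pytest
from hypothesis import settings

import splatsim as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_uniform():
    return ss.make_fixture("tiny-uniform", seed=0)


@pytest.fixture(scope="session")
def tiny_splat():
    return ss.make_fixture("tiny-splat", seed=0)


@pytest.fixture(scope="session")
def small_splat_result():
    """A modest single-population simulation reused across tests."""
    p = ss.update_params(
        ss.default_params("splat"),
        dict(n_genes=500, n_cells=80, seed=42, batch_cells=[80]),
    )
    return ss.splat_simulate(p)
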