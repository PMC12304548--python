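import numpy as np
import pytest

from costack import simulate
from costack.core_io import Frame


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured synthetic study: 120 cells on 256x256."""
    return simulate.default_config(n_cells=120, shape=(256, 256), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.simulate_tissue(small_config)


@pytest.fixture(scope="session")
def small_molecules(small_truth, small_config):
    return simulate.draw_cell_molecules(small_truth, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def frame():
    return Frame("he", (64, 64), 1.0)
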