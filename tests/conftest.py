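import numpy as np
import pytest

from stageloop import build_double_loop
from stageloop.pipeline import simulate_channel_matrix


@pytest.fixture(scope="session")
def full_design():
    """The study design: 40 stages, 80 arrays, 160 channels."""
    return build_double_loop(40)


@pytest.fixture(scope="session")
def small_design():
    return build_double_loop(5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def channel_matrix(design, n_genes, seed, **kw):
    """Log2 channel matrix straight from the analysis model (fast path)."""
    return simulate_channel_matrix(design, n_genes=n_genes, seed=seed, **kw)
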