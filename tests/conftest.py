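import numpy as np
import pytest

from methyltf import SimConfig, filter_low_expression, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small planted cohort shared by cheap end-to-end tests."""
    cfg = SimConfig(
        n_genes=120,
        promoter_length=300,
        n_tfs=3,
        n_active_tfs=1,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_expr(small_sim):
    return filter_low_expression(small_sim.expression.values, 0.10)


@pytest.fixture
def rng():
    return np.random.default_rng(20120532)
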