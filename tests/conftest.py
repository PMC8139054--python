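import numpy as np
import pytest

from michigan.simdata import SimConfig, SplatterSimulator, log1p_counts


@pytest.fixture(scope="session")
def small_linear_dataset():
    """Shared small splatter-style dataset (linear step), log1p processed."""
    cfg = SimConfig(n_cells=600, n_genes=120, step_mode="linear", seed=7)
    return log1p_counts(SplatterSimulator(cfg).sample(cfg.n_cells))


@pytest.fixture(scope="session")
def small_simulator():
    cfg = SimConfig(n_cells=600, n_genes=120, step_mode="linear", seed=7)
    return SplatterSimulator(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
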