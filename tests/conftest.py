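import numpy as np
import pytest

from multiline_gs.simdata import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale three-line dataset used by I/O and pipeline tests."""
    return SimulationConfig(
        seed=11,
        n_train_per_line=80,
        n_valid_per_line=30,
        n_markers=300,
        n_qtl=40,
        ld_rho=0.5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
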