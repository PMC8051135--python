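import numpy as np
import pytest

from chromenh.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale dataset shared across tests (read-only)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config for fast per-test generation."""
    return SimulationConfig(
        seed=5,
        chrom_lengths={"chr1": 400_000},
        n_genes=200,
        n_sites=60,
        signature_set_size=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
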