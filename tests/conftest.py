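from pathlib import Path

import numpy as np
import pytest

from mbdpipe.simulate import SimulationConfig, simulate_dataset, write_fixture_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SMALL_SIM = SimulationConfig(
    seed=42, n_genes=20, n_chroms=2, n_planted_dmrs=10,
    planted_degs={"L": (4, 2), "H": (3, 2), "VH": (2, 3)},
)


@pytest.fixture(scope="session")
def small_dataset():
    """20 genes, full-size cohort, 10 auto plants; shared across tests."""
    return simulate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory) -> Path:
    """The same small simulation written out as a file fixture tree."""
    out = tmp_path_factory.mktemp("fixture")
    write_fixture_set(SMALL_SIM, out)
    return out
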