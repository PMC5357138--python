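import numpy as np
import pytest

from cyclops_screen.config import RunConfig, SimConfig
from cyclops_screen.simulate import simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A small synthetic panel shared by read-only tests."""
    cfg = SimConfig(n_chromosomes=4, genes_per_arm=10, n_cell_lines=100,
                    n_junctions=120, seed=11)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig(seed=11, n_permutations=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
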