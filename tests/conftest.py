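import numpy as np
import pytest

from sulfostress.core import design_frame
from sulfostress.simulate import GeneratorConfig, simulate_all


@pytest.fixture(scope="session")
def design():
    return design_frame()


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale generator config for fast end-to-end tests."""
    return GeneratorConfig(n_genes=300, n_proteins=120, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth, tables = simulate_all(small_config)
    return truth, tables


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the full default scale (2644 genes, 1107 proteins)."""
    truth, tables = simulate_all(GeneratorConfig(seed=11))
    return truth, tables


@pytest.fixture
def rng():
    return np.random.default_rng(42)
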