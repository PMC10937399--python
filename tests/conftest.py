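import numpy as np
import pytest

from banksy import SyntheticConfig, generate

TOY_KWARGS = dict(n_cells=300, n_genes=30, n_markers_per_type=5, seed=7)
RESOLUTION_GRID = np.round(np.arange(0.1, 2.01, 0.1), 2)


@pytest.fixture(scope="session")
def toy_truth():
    """Small layered dataset (300 cells, 30 genes) for fast end-to-end tests."""
    return generate(SyntheticConfig(**TOY_KWARGS))


@pytest.fixture(scope="session")
def standard_truth():
    """The standard synthetic scenario at its default size (1200 cells)."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
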