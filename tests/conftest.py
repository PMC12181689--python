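import numpy as np
import pytest

from maxampo import PipelineConfig, run_pipeline
from maxampo.grid import Grid
from maxampo.synthetic_island import SyntheticIslandConfig, simulate_island


@pytest.fixture(scope="session")
def small_island():
    """A quick 64x64 island used by module-level tests."""
    return simulate_island(
        SyntheticIslandConfig(n_rows=64, n_cols=64, n_presence=150, seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_result():
    """The shipped synthetic benchmark: default island (low noise, 500
    presences), reduced ensemble size (20 models, 5 selected)."""
    cfg = PipelineConfig(n_models=20, k_best=5, master_seed=1)
    return run_pipeline(cfg)


@pytest.fixture
def unit_grid():
    """10x10 metric grid with 1 m cells, origin at (0, 10)."""
    return Grid(n_rows=10, n_cols=10, cell_size=1.0, origin=(0.0, 10.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
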