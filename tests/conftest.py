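import numpy as np
import pytest

from watercore.spectra import WavelengthGrid
from watercore.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def small_grid():
    # coarse grid for fast model tests
    return WavelengthGrid(np.linspace(350.0, 1050.0, 101))


@pytest.fixture(scope="session")
def clean_dataset(grid):
    """Noise-free, perfectly separable 4-class set (10 per class)."""
    cfg = GeneratorConfig(
        n_per_class=10, noise_sd=0.0, scatter_mult_sd=0.0, scatter_add_sd=0.0, seed=11
    )
    return generate_dataset(cfg, grid)


@pytest.fixture(scope="session")
def noisy_dataset(grid):
    """Default-noise 4-class set (25 per class) used across modules."""
    return generate_dataset(GeneratorConfig(n_per_class=25, seed=5), grid)
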