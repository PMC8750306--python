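import numpy as np
import pytest

from meatspec.dataset import ScanMeta, SpectralDataset, nir_grid
from meatspec.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_nir_dataset() -> SpectralDataset:
    """Two samples × 6 replicates on the NIR grid, deterministic content."""
    grid = nir_grid()
    rng = np.random.default_rng(7)
    X = rng.normal(1.0, 0.1, size=(12, grid.n_channels))
    meta = [
        ScanMeta("S1", "pork", "intact", r + 1) for r in range(6)
    ] + [ScanMeta("S2", "beef", "intact", r + 1) for r in range(6)]
    return SpectralDataset(X, grid, meta)


@pytest.fixture(scope="session")
def nir_campaign() -> SpectralDataset:
    """A moderately sized four-species NIR campaign (shared across tests)."""
    return generate_dataset(
        SimConfig(n_samples_per_species=8, sensor="nir", form="ground", seed=42)
    )


@pytest.fixture(scope="session")
def visnir_campaign() -> SpectralDataset:
    """A four-species Vis-NIR campaign with the default (separable) profiles."""
    return generate_dataset(
        SimConfig(n_samples_per_species=20, sensor="visnir", form="intact", seed=42)
    )
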