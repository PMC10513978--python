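import numpy as np
import pytest

import vqlobes as vq

#: Coarse grid used where geometry, not resolution, is under test.
COARSE_GRID = vq.VoxelGrid(shape=(64, 64, 64), spacing_mm=(6.6, 6.6, 6.6))


@pytest.fixture(scope="session")
def default_phantom() -> vq.Phantom:
    """Default-geometry phantom at the clinical SPECT grid (128^3, 3.3 mm)."""
    return vq.build_phantom(vq.PhantomSpec(), vq.DEFAULT_SPECT_GRID)


@pytest.fixture(scope="session")
def coarse_phantom() -> vq.Phantom:
    """Default-geometry phantom at a coarse grid, for cheap pipeline tests."""
    return vq.build_phantom(vq.PhantomSpec(), COARSE_GRID)


@pytest.fixture(scope="session")
def noiseless_spect(default_phantom) -> vq.SpectVolume:
    """Blurred (5 mm FWHM) but noise-free ventilation SPECT of the default
    phantom."""
    return vq.simulate_spect(default_phantom.activity_v, default_phantom.grid,
                             psf_fwhm_mm=5.0, total_counts=5e6, noise=False)


def uniform_mu_map(grid: vq.VoxelGrid, mu: float) -> vq.MuMap:
    return vq.MuMap(grid=grid, mu=np.full(grid.shape, mu))
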