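import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from odtquant import CompartmentDensities, OpticalConfig, RITomogram
from odtquant.phantom import make_cell_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """Desk-scale optical configuration: 0.25 µm isotropic voxels."""
    return OpticalConfig(voxel_size_um=(0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def phantom(config):
    """Default single-cell phantom (shared, read-only)."""
    return make_cell_phantom(config=config, shape=(128, 128, 128))


@pytest.fixture(scope="session")
def small_sphere(config):
    """Weak-contrast sphere (Δn = 0.002, r = 2 µm) on a 64³ grid."""
    n = 64
    ax = (np.arange(n) - (n - 1) / 2) * 0.25
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = z**2 + y**2 + x**2 <= 2.0**2
    vals = np.full((n, n, n), config.medium_ri)
    vals[mask] += 0.002
    return RITomogram(vals, config.voxel_size_um, config.medium_ri), mask
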