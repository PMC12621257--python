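import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import benchkit as bk

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def dense_grid():
    return np.arange(1.0, 6.0 + 1e-12, 0.002)


@pytest.fixture
def octahedron():
    """Ideal FeN6 octahedron, 2.0 angstrom bonds."""
    return bk.gen_octahedral_toy(bond_length=2.0, n_ligands=6)


@pytest.fixture
def single_stick():
    return bk.StickSpectrum([3.0], [1.0])


def gaussian_spectrum(center, sigma, grid, window=None):
    """Unit-height Gaussian as a Spectrum on the given grid."""
    y = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    y = y / y.max()
    if window is None:
        window = (float(grid[0]), float(grid[-1]))
    return bk.Spectrum(grid, y, window)
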