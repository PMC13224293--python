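import numpy as np
import pytest

from irmix import SuiteConfig, Spectrum, WavenumberGrid, generate_benchmark_suite
from irmix.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def grid():
    """The common 0-4996 cm^-1, 4 cm^-1 grid."""
    from irmix import DEFAULT_GRID

    return DEFAULT_GRID


@pytest.fixture
def small_grid():
    """A short grid for hand-computable examples."""
    return WavenumberGrid(start=0.0, step=4.0, n_points=16)


def gaussian_spectrum(grid, center, sigma=20.0):
    """Unit-area single-Gaussian spectrum on the given grid."""
    nu = grid.wavenumbers
    x = np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    return Spectrum(grid, x / (x.sum() * grid.step), normalized=True)


@pytest.fixture(scope="session")
def gas_suite():
    """Small strictly linear sharp-peak suite shared across tests."""
    cfg = SuiteConfig(
        n_molecules=40, n_binary=20, n_ternary=10, component_pool=16, phase="gas"
    )
    return generate_benchmark_suite(cfg, seed=7)
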