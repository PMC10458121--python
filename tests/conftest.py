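import numpy as np
import pytest

from adulterspec.spectra_core import WavelengthGrid, default_grid
from adulterspec.synthetic_data import MixDesign, generate_adulterant_set


@pytest.fixture(scope="session")
def grid():
    """Full-resolution instrument grid (2068 points, 200-1100 nm)."""
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 200-point grid for fast end-to-end runs."""
    return default_grid(200)


@pytest.fixture(scope="session")
def soybean_set(grid):
    """One default-design soybean adulterant set (64 samples, seed 0)."""
    return generate_adulterant_set("soybean", MixDesign(seed=0), grid)


@pytest.fixture(scope="session")
def planted_problem():
    """Regression problem with 5 planted informative variables out of 100.

    y is linear in the planted columns plus small noise; everything else is
    independent noise. Ground truth for selector-recall checks.
    """
    rng = np.random.default_rng(7)
    n, p = 60, 100
    X = rng.normal(size=(n, p))
    planted = np.array([10, 30, 50, 70, 90])
    y = X[:, planted] @ np.array([1.0, 0.9, 1.1, 1.0, 0.8])
    y = y + 0.05 * rng.normal(size=n)
    return X, y, planted
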