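import warnings

import numpy as np
import pytest

from pcell import PCellParams, extract_isosurface, sample_grid

# thin shells on coarse grids warn about under-resolution; tests choose
# their resolutions deliberately
warnings.filterwarnings("ignore", message="thickness .* under-resolved")


@pytest.fixture(scope="session")
def standard_params():
    """The standard P-cell: k = 0, s = 1, L = 2*pi mm, N = 100."""
    return PCellParams(k=0.0, s=1.0, N=100)


@pytest.fixture(scope="session")
def standard_field(standard_params):
    return sample_grid(standard_params)


@pytest.fixture(scope="session")
def standard_mesh(standard_field):
    return extract_isosurface(standard_field, 0.0)


@pytest.fixture(scope="session")
def coarse_params():
    """Faster 60^3 sampling for sweeps where trends, not anchors, matter."""
    return PCellParams(k=0.0, s=1.0, N=60)


@pytest.fixture(scope="session")
def coarse_field(coarse_params):
    return sample_grid(coarse_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
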