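import numpy as np
import pytest

from spectmcvar.grids import Grid3D, MuMap
from spectmcvar.phantoms import build_cylinder_sphere_phantom
from spectmcvar.projector import PSFModel, default_geometry


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid covering the same physical volume as the desk-scale grid."""
    return Grid3D((32, 32, 24), (9.6, 9.6, 9.6))


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return build_cylinder_sphere_phantom(small_grid)


@pytest.fixture(scope="session")
def small_geometry(small_grid):
    return default_geometry(small_grid, n_angles=8, radius=150.0)


@pytest.fixture(scope="session")
def psf():
    return PSFModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
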