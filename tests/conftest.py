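import numpy as np
import pytest
import trimesh

from limblab.core import SurfaceMesh, VoxelGrid
from limblab.phantom import PhantomSpec, make_limb_phantom
from limblab.surface import DecimationConfig, decimate_mesh, extract_isosurface


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_spec():
    # small grid keeps marching cubes and registration fast in the suite
    return PhantomSpec(
        shape=(48, 72, 36), spacing=(1.0, 1.0, 1.0), semi_axes=(18.0, 52.0, 12.0),
        noise_level=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_phantom_spec():
    return PhantomSpec(
        shape=(48, 72, 36), spacing=(1.0, 1.0, 1.0), semi_axes=(18.0, 52.0, 12.0),
        noise_level=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return make_limb_phantom(phantom_spec)


@pytest.fixture(scope="session")
def paddle_surface(phantom):
    return extract_isosurface(phantom["nuclei"], 50.0)


@pytest.fixture(scope="session")
def paddle_surface_coarse(paddle_surface):
    # decimated surface, as the registration stage would use
    return decimate_mesh(paddle_surface, DecimationConfig(target_reduction=0.95))


def icosphere(radius=1.0, subdivisions=3) -> SurfaceMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


@pytest.fixture
def sphere_grid():
    """Signed-distance sphere r=20 µm on a 0.5 µm grid, zero level at r."""
    n, sp, r = 97, 0.5, 20.0
    ax = (np.arange(n) - n // 2) * sp
    dist = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    return VoxelGrid(r - dist, (sp, sp, sp))
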