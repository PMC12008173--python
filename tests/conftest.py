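import numpy as np
import pytest

from cbmpet.config import PipelineConfig
from cbmpet.phantom import PhantomSpec, build_volume_phantom, make_icosphere, make_parcellation
from cbmpet.volumes import VolumeImage


@pytest.fixture(scope="session")
def mesh_s2():
    """162-vertex icosphere: cheap structural tests."""
    return make_icosphere(2, 40.0)


@pytest.fixture(scope="session")
def mesh_s4():
    """2562-vertex icosphere at hemisphere scale."""
    return make_icosphere(4, 85.0)


@pytest.fixture(scope="session")
def mesh_s5():
    """10242-vertex icosphere: fine mesh for kernel-accuracy checks."""
    return make_icosphere(5, 85.0)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(mesh_subdivisions=2, mesh_radius_mm=40.0, grid_shape=(24, 24, 24))


@pytest.fixture(scope="session")
def small_phantom(mesh_s2, small_spec):
    """(activity, labels) voxel phantom around the 162-vertex sphere."""
    return build_volume_phantom(mesh_s2, small_spec)


@pytest.fixture(scope="session")
def parcellation_s4(mesh_s4):
    return make_parcellation(mesh_s4, 12, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return VolumeImage(rng.random((16, 16, 16)), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def default_config():
    return PipelineConfig()
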