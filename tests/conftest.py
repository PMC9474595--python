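import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from autoplan.geometry import ImageGeometry
from autoplan.phantom import PhantomSpec, generate_phantom
from autoplan.plans import assemble_crt3d, assemble_fourfield

RX = 45.0


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default anatomy on a 5 mm grid: fast enough for per-module tests."""
    return generate_phantom(PhantomSpec(voxel_spacing=(5.0, 5.0, 5.0)))


@pytest.fixture(scope="session")
def default_phantom():
    """The study-condition phantom (2.5 mm grid)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def fourfield_default(default_phantom):
    """Assembled + normalized 4-field-box plan on the default phantom."""
    return assemble_fourfield(default_phantom, rx=RX)


@pytest.fixture(scope="session")
def crt3d_default(default_phantom):
    """Assembled + normalized 3D-CRT plan on the default phantom."""
    return assemble_crt3d(default_phantom, rx=RX)


@pytest.fixture(scope="session")
def fourfield_coarse(coarse_phantom):
    return assemble_fourfield(coarse_phantom, rx=RX)


@pytest.fixture()
def mm_grid():
    """Small 1 mm isotropic grid for exact geometric oracles."""
    return ImageGeometry((61, 61, 61), (1.0, 1.0, 1.0))


def sphere(geometry, center, radius):
    x, y, z = geometry.world_grids()
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2
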