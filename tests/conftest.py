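import numpy as np
import pytest

from vortexsim.mesh import MeshSpec, build_mesh, rectangular_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """10x10 random lattice on the unit square."""
    return build_mesh(MeshSpec(nx=10, ny=10, h=0.1, seed=42))


@pytest.fixture(scope="session")
def mesh_6x6():
    return build_mesh(MeshSpec(nx=6, ny=6, h=1 / 6, seed=7))


@pytest.fixture(scope="session")
def mesh_20x20():
    return build_mesh(MeshSpec(nx=20, ny=20, h=1 / 20, seed=3))


@pytest.fixture(scope="session")
def rect_mesh():
    """Rectangular-limit lattice (nodes at cell centers), spacing 0.1."""
    return rectangular_mesh(MeshSpec(nx=10, ny=10, h=0.1, seed=0))


@pytest.fixture(scope="session")
def big_mesh():
    """100x100 lattice with the default d = 0.5h, unit cells."""
    return build_mesh(MeshSpec(nx=100, ny=100, h=1.0, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
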