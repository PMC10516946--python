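import numpy as np
import pytest

from cleftgrade.mesh_io import TriangleMesh


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_mesh(rng):
    """A small random triangle soup with a scalar array."""
    verts = rng.normal(size=(50, 3))
    faces = rng.integers(0, 50, size=(30, 3))
    return TriangleMesh(verts, faces, {"heat": rng.random(50)})


@pytest.fixture
def single_triangle():
    """One triangle in the z=0 plane, centered at the origin."""
    return TriangleMesh(
        np.array([[-0.5, -0.4, 0.0], [0.5, -0.4, 0.0], [0.0, 0.6, 0.0]]),
        np.array([[0, 1, 2]]),
    )
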