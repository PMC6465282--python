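import numpy as np
import pytest

from densephen import make_surface


@pytest.fixture(scope="session")
def icosphere():
    return make_surface("icosphere", subdivisions=2)


@pytest.fixture(scope="session")
def bumpy():
    return make_surface("bumpy_sphere", subdivisions=3, seed=3)


@pytest.fixture(scope="session")
def face_family():
    """Face-like template, its 19 ground-truth landmarks, and landmark vertex ids."""
    return make_surface("face_like", subdivisions=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid_mesh(nx: int = 4, ny: int = 4):
    """Planar triangulated grid (z=0), nx × ny vertices."""
    from densephen import TriangleMesh

    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append([a, a + 1, a + nx])
            faces.append([a + 1, a + nx + 1, a + nx])
    return TriangleMesh(verts, np.asarray(faces))
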