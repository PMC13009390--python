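import numpy as np
import pytest
import trimesh

from gplkit.mesh_io import TriMesh


@pytest.fixture
def tetrahedron() -> TriMesh:
    """Smallest closed mesh: the unit tetrahedron."""
    return TriMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
        np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
        name="tetra",
    )


def random_closed_mesh(rng: np.random.Generator, n_points: int = 50) -> TriMesh:
    """Random watertight mesh: convex hull of a Gaussian point cloud."""
    hull = trimesh.convex.convex_hull(rng.normal(size=(n_points, 3)) * 10.0)
    return TriMesh(np.asarray(hull.vertices, float), np.asarray(hull.faces))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
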