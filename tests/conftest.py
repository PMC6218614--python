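import numpy as np
import pytest

import cortical_loreta as cl


@pytest.fixture(scope="session")
def tetra() -> cl.TriMesh:
    """Regular tetrahedron (side 2*sqrt(2)): smallest closed mesh, all
    vertex pairs adjacent."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return cl.TriMesh(v, f)


@pytest.fixture(scope="session")
def unit_tetra(tetra) -> cl.TriMesh:
    """Regular tetrahedron with unit edge length."""
    side = np.linalg.norm(tetra.vertices[0] - tetra.vertices[1])
    return cl.TriMesh(tetra.vertices / side, tetra.triangles)


@pytest.fixture(scope="session")
def icosphere2() -> cl.TriMesh:
    return cl.make_icosphere(2, radius=80.0)


@pytest.fixture(scope="session")
def cortex300() -> cl.TriMesh:
    return cl.make_cortex_like_surface(300, seed=5)


@pytest.fixture(scope="session")
def planar_grid() -> cl.TriMesh:
    """Triangulated unit square in the z=0 plane (interior vertices exist)."""
    n = 6
    xs = np.linspace(0.0, 1.0, n)
    verts = np.array([[x, y, 0.0] for y in xs for x in xs])
    tris = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return cl.TriMesh(verts, np.array(tris))


@pytest.fixture(scope="session")
def small_inverse_setup():
    """162-node icosphere cortex, 32-channel montage and its leadfield."""
    mesh = cl.make_icosphere(2, radius=70.0)
    montage = cl.make_equidistant_montage(32, 85.0, 140.0)
    L = cl.spherical_leadfield(montage, cl.SourceSpace(mesh.vertices, mesh=mesh))
    return mesh, montage, L
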