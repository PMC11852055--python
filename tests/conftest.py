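import numpy as np
import pytest

from kneesim import fixtures
from kneesim.mesh import TriMesh


@pytest.fixture(scope="session")
def geometry():
    return fixtures.make_knee_geometry()


@pytest.fixture(scope="session")
def model(geometry):
    return geometry.build_model()


def make_plate(
    size: float = 10.0,
    n: int = 11,
    z: float = 0.0,
    normal_up: bool = True,
    label: str = "plate",
) -> TriMesh:
    """Square plate mesh in the z-plane with outward normal +z or -z."""
    xs = np.linspace(-size / 2, size / 2, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j  # (x_i, y_j)
            b = a + 1  # (x_i, y_j+1)
            c = a + n  # (x_i+1, y_j)
            d = c + 1  # (x_i+1, y_j+1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    faces = np.asarray(faces)
    if not normal_up:
        faces = faces[:, ::-1]
    return TriMesh(verts, faces, label)


def make_sphere_surface(
    radius: float,
    center,
    n_theta: int = 24,
    n_phi: int = 48,
    theta_max_deg: float = 90.0,
    pole_dir=(0, 0, -1),
) -> TriMesh:
    """Lower spherical cap with outward-radial normals (test master body)."""
    center = np.asarray(center, float)
    d = np.asarray(pole_dir, float)
    d = d / np.linalg.norm(d)
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    thetas = np.linspace(0, np.deg2rad(theta_max_deg), n_theta + 1)[1:]
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    verts = [center + radius * d]
    for th in thetas:
        for ph in phis:
            direction = (
                np.cos(th) * d + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)
            )
            verts.append(center + radius * direction)
    verts = np.asarray(verts)
    faces = []
    for j in range(n_phi):
        faces.append([0, 1 + (j + 1) % n_phi, 1 + j])
    for i in range(n_theta - 1):
        base = 1 + i * n_phi
        nxt = base + n_phi
        for j in range(n_phi):
            j1 = (j + 1) % n_phi
            faces.append([base + j, base + j1, nxt + j1])
            faces.append([base + j, nxt + j1, nxt + j])
    mesh = TriMesh(verts, np.asarray(faces), "sphere")
    # Orient all faces radially outward.
    fn = mesh.face_normals()
    cen = mesh.face_centroids() - center
    cen /= np.linalg.norm(cen, axis=1, keepdims=True)
    flip = np.einsum("ij,ij->i", fn, cen) < 0
    mesh.faces[flip] = mesh.faces[flip][:, ::-1]
    return mesh
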