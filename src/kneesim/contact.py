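"""Elastic-foundation contact between triangle surfaces.

Each of the five knee contact pairs couples a moving "slave" surface
(tibial cartilage, meniscus or patellar cartilage) to the femoral cartilage
"master".  Per slave vertex, the penetration depth is found by casting a
ray backward along the vertex normal against the master surface; the vertex
force is ``PM * A_i * d_i`` (pressure module x tributary area x depth),
compressive only, directed against the slave vertex normal, with the equal
and opposite reaction applied to the master body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from kneesim.errors import ConfigurationError, DomainError
from kneesim.kinematics import Pose
from kneesim.mesh import TriMesh

#: Largest penetration considered physical (mm); deeper ray hits are
#: rejected (they are geometric artefacts, e.g. the far side of a body).
MAX_DEPTH = 6.0


@dataclass(frozen=True)
class Material:
    """Linear elastic layer: modulus E (MPa), Poisson ratio v, thickness h (mm)."""

    E: float
    v: float
    h: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise DomainError("elasticity modulus must be positive")
        if not 0 <= self.v < 0.5:
            raise DomainError("Poisson ratio must lie in [0, 0.5)")
        if self.h <= 0:
            raise DomainError("layer thickness must be positive")


#: Default material table for the six contacting tissues.
DEFAULT_MATERIALS: dict[str, Material] = {
    "femoral_cartilage": Material(E=5.0, v=0.46, h=2.2),
    "medial_tibial_cartilage": Material(E=5.0, v=0.46, h=2.1),
    "lateral_tibial_cartilage": Material(E=5.0, v=0.46, h=2.6),
    "medial_meniscus": Material(E=59.0, v=0.49, h=3.5),
    "lateral_meniscus": Material(E=59.0, v=0.49, h=3.2),
    "patellar_cartilage": Material(E=5.0, v=0.46, h=3.3),
}


def pressure_module(m1: Material, m2: Material) -> float:
    """Composite layer stiffness per unit depth (MPa/mm).

    ``PM = [ g(v1) h1/E1 + g(v2) h2/E2 ]^-1`` with
    ``g(v) = (1+v)(1-2v)/(1-v)``; symmetric in its operands and unbounded
    as either layer approaches incompressibility.
    """

    def compliance(m: Material) -> float:
        if m.v >= 0.5 - 1e-9:
            raise DomainError("incompressible layer: pressure module unbounded")
        return (1 + m.v) * (1 - 2 * m.v) / (1 - m.v) * m.h / m.E

    return 1.0 / (compliance(m1) + compliance(m2))


@dataclass
class ContactPair:
    """Slave/master surface pair with bound materials and pressure module.

    ``master_compartment`` optionally restricts the master to faces carrying
    that tag (e.g. each tibiofemoral pair casts only against its own condyle
    of the shared femoral cartilage).
    """

    name: str
    slave: TriMesh
    slave_material: Material
    master: TriMesh
    master_material: Material
    master_compartment: str | None = None
    pm: float = field(init=False)

    def __post_init__(self) -> None:
        self.pm = pressure_module(self.slave_material, self.master_material)


@dataclass
class ContactResult:
    """Per-vertex contact state and aggregated wrenches for one pair."""

    pair_name: str
    points: np.ndarray  # world application points on the slave (n,3)
    depths: np.ndarray  # penetration depths (mm), 0 when apart
    areas: np.ndarray  # tributary areas (mm^2)
    forces: np.ndarray  # force magnitudes PM*A*d (N), >= 0
    directions: np.ndarray  # unit force directions on the slave body
    compartments: np.ndarray  # per-vertex tag

    @property
    def n_contacting(self) -> int:
        return int(np.count_nonzero(self.depths > 0))

    def force_vectors(self) -> np.ndarray:
        return self.forces[:, None] * self.directions

    def resultant_on_slave(self) -> np.ndarray:
        return self.force_vectors().sum(axis=0)

    def resultant_on_master(self) -> np.ndarray:
        return -self.resultant_on_slave()

    def moment_on_slave(self, about: np.ndarray) -> np.ndarray:
        r = self.points - np.asarray(about, float)
        return np.cross(r, self.force_vectors()).sum(axis=0)

    def compartment_resultants(self) -> dict[str, np.ndarray]:
        out = {}
        for comp in ("medial", "lateral", "none"):
            sel = self.compartments == comp
            out[comp] = self.force_vectors()[sel].sum(axis=0)
        return out


class PairContactEngine:
    """Ray-cast penetration queries for one pair, with cached acceleration.

    The master triangle soup and its centroid KD-tree live in the master
    body frame, so they are built once; per query only the slave vertices
    are mapped into that frame.  Candidate triangle sets are reused across
    nearby queries (finite-difference perturbations) until the slave moves
    more than half the cache margin.
    """

    def __init__(self, pair: ContactPair, margin: float = 4.0):
        self.pair = pair
        self.margin = float(margin)
        m = pair.master
        faces = m.faces
        if pair.master_compartment is not None:
            faces = faces[m.compartment == pair.master_compartment]
        self.tri = m.vertices[faces]  # (T,3,3)
        self.tri_a = np.ascontiguousarray(self.tri[:, 0])
        self.tri_e1 = np.ascontiguousarray(self.tri[:, 1] - self.tri[:, 0])
        self.tri_e2 = np.ascontiguousarray(self.tri[:, 2] - self.tri[:, 0])
        self.tri_normal = _cross(self.tri_e1, self.tri_e2)
        centroids = self.tri.mean(axis=1)
        self.circumradius = float(
            np.sqrt(((self.tri - centroids[:, None, :]) ** 2).sum(-1).max())
        )
        self.tree = cKDTree(centroids)
        s = pair.slave
        self.slave_local = s.vertices.copy()
        self.slave_normals_local = s.vertex_normals()
        self.areas = s.tributary_areas()
        self.vertex_comp = s.vertex_compartments()
        self._cache_pts: np.ndarray | None = None
        self._cache_rays: np.ndarray | None = None
        self._cache_tris: np.ndarray | None = None

    def _candidates(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._cache_pts is not None and len(self._cache_pts) == len(pts):
            if np.abs(pts - self._cache_pts).max() < 0.5 * self.margin:
                return self._cache_rays, self._cache_tris
        radius = self.circumradius + MAX_DEPTH / 2 + self.margin
        lists = self.tree.query_ball_point(pts, r=radius)
        lengths = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
        ray_idx = np.repeat(np.arange(len(pts)), lengths)
        tri_idx = (
            np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
            if lengths.sum()
            else np.zeros(0, dtype=np.int64)
        )
        self._cache_pts = pts.copy()
        self._cache_rays, self._cache_tris = ray_idx, tri_idx
        return ray_idx, tri_idx

    def depths(
        self, pose_slave: Pose, pose_master: Pose
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-vertex penetration depths; also returns world points/normals."""
        rel = pose_master.inverse().compose(pose_slave)
        pts = rel.apply(self.slave_local)
        normals = self.slave_normals_local @ rel.rotation.T
        ray_idx, tri_idx = self._candidates(pts)
        depths = np.full(len(pts), np.inf)
        if len(ray_idx):
            t = _ray_hits(
                pts[ray_idx],
                -normals[ray_idx],
                self.tri_a[tri_idx],
                self.tri_e1[tri_idx],
                self.tri_e2[tri_idx],
                self.tri_normal[tri_idx],
                normals[ray_idx],
            )
            finite = np.isfinite(t)
            np.minimum.at(depths, ray_idx[finite], t[finite])
        depths[~np.isfinite(depths)] = 0.0
        world_pts = pose_master.apply(pts)
        world_normals = normals @ pose_master.rotation.T
        return depths, world_pts, world_normals


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis gymnastics."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1] + a[:, 2] * b[:, 2]


def _ray_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    tri_a: np.ndarray,
    tri_e1: np.ndarray,
    tri_e2: np.ndarray,
    tri_normals: np.ndarray,
    slave_normals: np.ndarray,
) -> np.ndarray:
    """Moeller-Trumbore distances for (ray, triangle) pairs; inf when missed.

    Only master faces oriented against the slave normal count (the surface
    facing the slave body); hits beyond :data:`MAX_DEPTH` are rejected.
    """
    h = _cross(directions, tri_e2)
    det = _dot(tri_e1, h)
    facing = _dot(tri_normals, slave_normals) < 0.0
    ok = (np.abs(det) > 1e-12) & facing
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    s = origins - tri_a
    u = _dot(s, h) * inv
    q = _cross(s, tri_e1)
    v = _dot(directions, q) * inv
    t = _dot(tri_e2, q) * inv
    eps = 1e-9
    ok &= (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= 0.0) & (t <= MAX_DEPTH)
    return np.where(ok, t, np.inf)


def vertex_penetrations(
    pair: ContactPair,
    pose_slave: Pose | None = None,
    pose_master: Pose | None = None,
    engine: PairContactEngine | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex penetration depths and tributary areas for a pair."""
    engine = engine or PairContactEngine(pair)
    depths, _, _ = engine.depths(
        pose_slave or Pose.identity(), pose_master or Pose.identity()
    )
    return depths, engine.areas


def contact_forces(
    pair: ContactPair,
    pose_slave: Pose | None = None,
    pose_master: Pose | None = None,
    engine: PairContactEngine | None = None,
) -> ContactResult:
    """Elastic-foundation contact forces ``F_i = PM * A_i * d_i`` for a pair."""
    engine = engine or PairContactEngine(pair)
    pose_slave = pose_slave or Pose.identity()
    pose_master = pose_master or Pose.identity()
    depths, world_pts, world_normals = engine.depths(pose_slave, pose_master)
    forces = pair.pm * engine.areas * depths
    return ContactResult(
        pair_name=pair.name,
        points=world_pts,
        depths=depths,
        areas=engine.areas,
        forces=forces,
        directions=-world_normals,
        compartments=engine.vertex_comp,
    )


#: Pair name -> (slave surface key, master femoral-cartilage compartment)
DEFAULT_PAIR_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("medial_tibiofemoral", "medial_tibial_cartilage", "medial"),
    ("lateral_tibiofemoral", "lateral_tibial_cartilage", "lateral"),
    ("medial_meniscofemoral", "medial_meniscus", "medial"),
    ("lateral_meniscofemoral", "lateral_meniscus", "lateral"),
    ("patellofemoral", "patellar_cartilage", "none"),
)


def build_default_pairs(
    surfaces: dict[str, TriMesh],
    materials: dict[str, Material] | None = None,
) -> list[ContactPair]:
    """The five default contact pairs, all sharing the femoral cartilage master."""
    materials = materials or DEFAULT_MATERIALS
    missing = [
        key
        for key in ["femoral_cartilage"] + [s for _, s, _ in DEFAULT_PAIR_LAYOUT]
        if key not in surfaces
    ]
    if missing:
        raise ConfigurationError(f"missing contact surfaces: {missing}")
    master = surfaces["femoral_cartilage"]
    master_mat = materials["femoral_cartilage"]
    return [
        ContactPair(
            name=name,
            slave=surfaces[slave_key],
            slave_material=materials[slave_key],
            master=master,
            master_material=master_mat,
            master_compartment=master_comp,
        )
        for name, slave_key, master_comp in DEFAULT_PAIR_LAYOUT
    ]
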