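"""Seeded synthetic fixtures: parametric knee geometry, ligament/muscle
attachments, five-activity motion and ground-reaction profiles, virtual
marker trajectories, and pseudo-reference curves for metric testing.

Frame conventions (femur reference frame at full extension): x = medial,
y = anterior, z = superior; the flexion axis is the x-axis through the
origin, which carries both condyle sphere centers so that the articulating
femoral surfaces are invariant under flexion.  The laboratory frame of the
synthetic motion capture coincides with the tibia anatomical frame (the
tibia is the static body of the desk-scale rig; the femur flexes above it).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from kneesim.contact import DEFAULT_MATERIALS, Material, build_default_pairs
from kneesim.errors import DomainError
from kneesim.fdk import Trial
from kneesim.kinematics import (
    JointDefinition,
    KneeDofState,
    MarkerModel,
    Pose,
    flexion_from_relative_pose,
    pose_from_markers,
    tibia_pose_from_dofs,
)
from kneesim.ligaments import LigamentBundle, default_bundle_table
from kneesim.mesh import TriMesh, combine
from kneesim.metrics import ACTIVITIES, Curve, N_CYCLE_POINTS
from kneesim.model import KneeModel
from kneesim.recruitment import MuscleUnit, intersegmental_load, resample_to

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class KneeFixtureParams:
    """Geometric and subject parameters of the parametric knee."""

    medial_condyle_radius: float = 22.0
    lateral_condyle_radius: float = 21.0
    condyle_offset: float = 23.0  # |x| of each condyle center (mm)
    medial_dish_radius: float = 26.0  # concave plateau radius (mm)
    lateral_dish_radius: float = 30.0
    dish_plan_radius: float = 13.0  # plateau footprint radius (mm)
    trochlea_radius: float = 24.0
    cartilage_gap: float = 0.25  # tibiofemoral clearance at reference (mm)
    meniscus_gap: float = 0.45
    patellar_gap: float = 0.30
    subject_mass_kg: float = 73.4
    subject_height_m: float = 1.78
    mesh_density: float = 1.0  # multiplies angular/grid sample counts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "medial_condyle_radius",
            "lateral_condyle_radius",
            "condyle_offset",
            "medial_dish_radius",
            "lateral_dish_radius",
            "dish_plan_radius",
            "trochlea_radius",
            "cartilage_gap",
            "meniscus_gap",
            "patellar_gap",
            "subject_mass_kg",
            "subject_height_m",
            "mesh_density",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.medial_dish_radius <= self.medial_condyle_radius:
            raise DomainError("medial dish must be flatter than the condyle")
        if self.lateral_dish_radius <= self.lateral_condyle_radius:
            raise DomainError("lateral dish must be flatter than the condyle")


# ---------------------------------------------------------------------------
# Parametric surface helpers
# ---------------------------------------------------------------------------


def _orient_faces(mesh: TriMesh, desired_normals) -> TriMesh:
    """Flip any face whose winding disagrees with the analytic normal field.

    ``desired_normals(points) -> unit vectors``; valid for smooth parametric
    surfaces, and guarantees orientation consistency with that field.
    """
    fn = mesh.face_normals()
    want = desired_normals(mesh.face_centroids())
    bad = np.einsum("ij,ij->i", fn, want) < 0.0
    faces = mesh.faces.copy()
    faces[bad] = faces[bad][:, ::-1]
    return TriMesh(mesh.vertices, faces, mesh.label, mesh.compartment)


def _grid_to_mesh(
    pts: np.ndarray, wrap_v: bool, flip: bool, label: str, compartment: str
) -> TriMesh:
    """Triangulate an (nu, nv, 3) structured grid; optionally wrap in v."""
    nu, nv, _ = pts.shape
    verts = pts.reshape(-1, 3)
    faces = []
    vmax = nv if wrap_v else nv - 1
    for i in range(nu - 1):
        for j in range(vmax):
            j1 = (j + 1) % nv
            a = i * nv + j
            b = i * nv + j1
            c = (i + 1) * nv + j
            d = (i + 1) * nv + j1
            faces.append([a, b, d])
            faces.append([a, d, c])
    faces = np.asarray(faces)
    if flip:
        faces = faces[:, ::-1]
    comp = np.full(len(faces), compartment, dtype="<U7")
    return TriMesh(verts, faces, label, comp)


def _sphere_cap(
    center: np.ndarray,
    radius: float,
    pole_dir: np.ndarray,
    theta_max_deg: float,
    n_theta: int,
    n_phi: int,
    concave: bool,
    label: str,
    compartment: str,
) -> TriMesh:
    """Spherical cap around ``pole_dir``; convex caps get outward-radial
    normals, concave caps (plateau dishes) inward-radial."""
    center = np.asarray(center, float)
    d = np.asarray(pole_dir, float)
    d = d / np.linalg.norm(d)
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    thetas = np.linspace(0.0, np.deg2rad(theta_max_deg), n_theta + 1)[1:]
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    rings = np.empty((n_theta, n_phi, 3))
    for i, th in enumerate(thetas):
        ring_dir = (
            np.cos(th) * d
            + np.sin(th) * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
        )
        rings[i] = center + radius * ring_dir
    body = _grid_to_mesh(rings, wrap_v=True, flip=concave, label=label,
                         compartment=compartment)
    # Close the pole with a triangle fan.
    pole = center + radius * d
    verts = np.vstack([body.vertices, pole])
    p = len(verts) - 1
    fan = []
    for j in range(n_phi):
        j1 = (j + 1) % n_phi
        fan.append([p, j1, j] if not concave else [p, j, j1])
    faces = np.vstack([body.faces, np.asarray(fan)])
    comp = np.concatenate(
        [body.compartment, np.full(n_phi, compartment, dtype="<U7")]
    )
    sign = -1.0 if concave else 1.0

    def radial(pts: np.ndarray) -> np.ndarray:
        v = pts - center
        return sign * v / np.linalg.norm(v, axis=1, keepdims=True)

    return _orient_faces(TriMesh(verts, faces, label, comp), radial)


def _cylinder_patch(
    radius: float,
    x_range: tuple[float, float],
    phi_range_deg: tuple[float, float],
    n_x: int,
    n_phi: int,
    concave: bool,
    label: str,
    compartment: str = "none",
) -> TriMesh:
    """Patch of a cylinder about the x-axis; phi measured from +y toward +z."""
    xs = np.linspace(*x_range, n_x)
    phis = np.deg2rad(np.linspace(*phi_range_deg, n_phi))
    pts = np.empty((n_x, n_phi, 3))
    pts[..., 0] = xs[:, None]
    pts[..., 1] = radius * np.cos(phis)[None, :]
    pts[..., 2] = radius * np.sin(phis)[None, :]
    sign = -1.0 if concave else 1.0

    def radial(p: np.ndarray) -> np.ndarray:
        v = p * [0.0, 1.0, 1.0]
        return sign * v / np.linalg.norm(v, axis=1, keepdims=True)

    return _orient_faces(
        _grid_to_mesh(pts, wrap_v=False, flip=False, label=label,
                      compartment=compartment),
        radial,
    )


def _meniscus_ring(
    center_x: float,
    condyle_radius: float,
    gap: float,
    rho_range: tuple[float, float],
    psi_range_deg: tuple[float, float],
    n_rho: int,
    n_psi: int,
    label: str,
    compartment: str,
) -> TriMesh:
    """C-shaped superior meniscus surface hugging its condyle at ``gap``."""
    rg = condyle_radius + gap
    rhos = np.linspace(*rho_range, n_rho)
    psis = np.deg2rad(np.linspace(*psi_range_deg, n_psi))
    pts = np.empty((n_rho, n_psi, 3))
    for i, rho in enumerate(rhos):
        z = -np.sqrt(rg**2 - rho**2)
        pts[i, :, 0] = center_x + rho * np.cos(psis)
        pts[i, :, 1] = rho * np.sin(psis)
        pts[i, :, 2] = z
    center = np.array([center_x, 0.0, 0.0])

    def toward_condyle(p: np.ndarray) -> np.ndarray:
        v = center - p
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    return _orient_faces(
        _grid_to_mesh(pts, wrap_v=False, flip=False, label=label,
                      compartment=compartment),
        toward_condyle,
    )


def _icosphere(center, radii, subdiv: int, label: str) -> TriMesh:
    """Closed ellipsoid from a subdivided icosahedron (watertight)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdiv):
        mids: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in mids:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                verts_list.append(m)
                mids[key] = len(verts_list) - 1
            return mids[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    verts = verts * np.asarray(radii, float) + np.asarray(center, float)
    return TriMesh(verts, faces, label)


# ---------------------------------------------------------------------------
# Knee geometry fixture
# ---------------------------------------------------------------------------


@dataclass
class KneeGeometry:
    """Generated surfaces, attachment tables and marker models."""

    params: KneeFixtureParams
    surfaces: dict[str, TriMesh]
    bones: dict[str, TriMesh]
    joint: JointDefinition
    ligament_bundles: list[LigamentBundle]
    muscles: list[MuscleUnit]
    femur_markers: MarkerModel
    tibia_markers: MarkerModel

    def build_model(
        self,
        materials: dict[str, Material] | None = None,
        moment_lever_mm: float = 10.0,
    ) -> KneeModel:
        pairs = build_default_pairs(self.surfaces, materials or DEFAULT_MATERIALS)
        pair_bodies = ["tibia", "tibia", "tibia", "tibia", "patella"]
        pair_comps = ["medial", "lateral", "medial", "lateral", "none"]
        return KneeModel(
            joint=self.joint,
            pairs=pairs,
            pair_bodies=pair_bodies,
            pair_compartments=pair_comps,
            ligament_bundles=self.ligament_bundles,
            muscles=self.muscles,
            subject_mass_kg=self.params.subject_mass_kg,
            moment_lever_mm=moment_lever_mm,
            surfaces=self.surfaces,
        )


#: Ligament attachment lines (bundle -> origin body/point, insertion
#: body/point), femur reference coordinates (mm).  Plausible anatomical
#: positions on the parametric surfaces; fixture configuration, not anatomy.
_LIGAMENT_ATTACHMENTS: dict[str, tuple[str, tuple, str, tuple]] = {
    "aACL": ("femur", (-7, -6, 2), "tibia", (1, 9, -24)),
    "pACL": ("femur", (-8, -9, 4), "tibia", (-1, 5, -24)),
    "aPCL": ("femur", (7, -2, -1), "tibia", (1, -13, -28)),
    "pPCL": ("femur", (8, -5, 3), "tibia", (-1, -16, -27)),
    "aLCL": ("femur", (-44, 3, 1), "tibia", (-40, -3, -45)),
    "mLCL": ("femur", (-44, 0, 1), "tibia", (-40, -6, -45)),
    "pLCL": ("femur", (-44, -3, 1), "tibia", (-40, -9, -45)),
    "aMCL": ("femur", (44, 4, 2), "tibia", (40, 6, -50)),
    "mMCL": ("femur", (44, 1, 2), "tibia", (40, 1, -50)),
    "pMCL": ("femur", (44, -2, 2), "tibia", (40, -4, -50)),
    "aDMCL": ("femur", (43, 2, 0), "tibia", (41, 2, -28)),
    "pDMCL": ("femur", (43, -4, 0), "tibia", (41, -4, -28)),
    "sMPFL": ("femur", (44, 6, 3), "patella", (11, 24, 20)),
    "mMPFL": ("femur", (44, 6, 1), "patella", (11, 25, 15)),
    "iMPFL": ("femur", (44, 6, -1), "patella", (11, 24, 10)),
    "sLPFL": ("femur", (-44, 6, 3), "patella", (-11, 24, 20)),
    "mLPFL": ("femur", (-44, 6, 1), "patella", (-11, 25, 15)),
    "iLPFL": ("femur", (-44, 6, -1), "patella", (-11, 24, 10)),
    "PMC": ("femur", (40, -12, -2), "tibia", (32, -16, -35)),
    "POL": ("femur", (42, -14, 0), "tibia", (30, -20, -35)),
    "ALL": ("femur", (-43, -1, 0), "tibia", (-35, 5, -30)),
    "PFL": ("femur", (-40, -12, -3), "tibia", (-38, -13, -42)),
}

#: Reduced lower-limb muscle construct: 4 quadriceps acting on the patella
#: (through the rigid patellar tendon), 2 hamstrings and 2 gastrocnemii on
#: the tibia.  Proximal origins are reduced to femur-fixed points.
_MUSCLE_TABLE: tuple[tuple[str, float, float, str, tuple, str, tuple], ...] = (
    ("vastus_medialis", 220.0, 8.0, "femur", (10, 14, 90), "patella", (5, 27, 22)),
    ("vastus_lateralis", 250.0, 8.0, "femur", (-10, 14, 90), "patella", (-5, 27, 22)),
    ("vastus_intermedius", 200.0, 8.5, "femur", (0, 16, 95), "patella", (0, 26, 23)),
    ("rectus_femoris", 270.0, 7.5, "femur", (0, 20, 110), "patella", (0, 28, 24)),
    ("semitendinosus", 200.0, 10.0, "femur", (15, -22, 100), "tibia", (25, -18, -35)),
    ("biceps_femoris", 250.0, 10.0, "femur", (-15, -22, 100), "tibia", (-30, -15, -38)),
    ("gastrocnemius_med", 140.0, 6.0, "femur", (15, -21, 10), "tibia", (5, -28, -150)),
    ("gastrocnemius_lat", 120.0, 6.0, "femur", (-15, -21, 10), "tibia", (-5, -28, -150)),
)


def make_knee_geometry(params: KneeFixtureParams | None = None) -> KneeGeometry:
    """Generate the parametric knee: 6 tissue surfaces, 3 bones, attachments.

    Geometry is deterministic (the seed governs only downstream noise).
    Condyle sphere centers sit on the flexion axis, so the femoral
    articulating surfaces are flexion-invariant; plateau dishes and menisci
    keep clearances ``cartilage_gap``/``meniscus_gap`` at reference.
    """
    p = params or KneeFixtureParams()
    dens = p.mesh_density
    nt = max(10, round(17 * dens))
    nphi = max(12, round(28 * dens))

    # Condylar caps wrap 150 deg of polar angle so the articulating zone
    # stays covered through deep flexion (the sphere centers sit on the
    # flexion axis, so the surface itself is flexion-invariant).
    def cap(sign: float, radius: float, comp: str) -> TriMesh:
        return _sphere_cap(
            center=(sign * p.condyle_offset, 0.0, 0.0),
            radius=radius,
            pole_dir=(0, 0, -1),
            theta_max_deg=150.0,
            n_theta=nt,
            n_phi=nphi,
            concave=False,
            label="femoral_cartilage",
            compartment=comp,
        )

    # The trochlear groove extends below the flexion axis so the patella can
    # ride distally in deep flexion.
    trochlea = _cylinder_patch(
        radius=p.trochlea_radius,
        x_range=(-8.0, 8.0),
        phi_range_deg=(-100.0, 62.0),
        n_x=max(5, round(8 * dens)),
        n_phi=max(16, round(30 * dens)),
        concave=False,
        label="femoral_cartilage",
    )
    femoral_cartilage = combine(
        [cap(+1, p.medial_condyle_radius, "medial"),
         cap(-1, p.lateral_condyle_radius, "lateral"),
         trochlea],
        label="femoral_cartilage",
    )

    def dish(sign: float, condyle_r: float, dish_r: float, comp: str) -> TriMesh:
        bottom = -(condyle_r + p.cartilage_gap)
        center = np.array([sign * p.condyle_offset, 0.0, bottom + dish_r])
        theta_max = np.rad2deg(np.arcsin(p.dish_plan_radius / dish_r))
        return _sphere_cap(
            center=center,
            radius=dish_r,
            pole_dir=(0, 0, -1),
            theta_max_deg=theta_max,
            n_theta=max(5, round(7 * dens)),
            n_phi=max(10, round(20 * dens)),
            concave=True,
            label=f"{comp}_tibial_cartilage",
            compartment=comp,
        )

    med_tibial = dish(+1, p.medial_condyle_radius, p.medial_dish_radius, "medial")
    lat_tibial = dish(-1, p.lateral_condyle_radius, p.lateral_dish_radius, "lateral")

    def meniscus(sign: float, condyle_r: float, comp: str) -> TriMesh:
        return _meniscus_ring(
            center_x=sign * p.condyle_offset,
            condyle_radius=condyle_r,
            gap=p.meniscus_gap,
            rho_range=(p.dish_plan_radius - 3.0, p.dish_plan_radius + 3.0),
            psi_range_deg=(25.0, 335.0),
            n_rho=max(3, round(4 * dens)),
            n_psi=max(12, round(24 * dens)),
            label=f"{comp}_meniscus",
            compartment=comp,
        )

    med_meniscus = meniscus(+1, p.medial_condyle_radius, "medial")
    lat_meniscus = meniscus(-1, p.lateral_condyle_radius, "lateral")

    patellar_cartilage = _cylinder_patch(
        radius=p.trochlea_radius + p.patellar_gap,
        x_range=(-6.0, 6.0),
        phi_range_deg=(12.0, 48.0),
        n_x=max(5, round(8 * dens)),
        n_phi=max(6, round(10 * dens)),
        concave=True,
        label="patellar_cartilage",
    )

    surfaces = {
        "femoral_cartilage": femoral_cartilage,
        "medial_tibial_cartilage": med_tibial,
        "lateral_tibial_cartilage": lat_tibial,
        "medial_meniscus": med_meniscus,
        "lateral_meniscus": lat_meniscus,
        "patellar_cartilage": patellar_cartilage,
    }
    bones = {
        "femur": _icosphere((0, 0, 55), (34, 28, 75), 2, "femur"),
        "tibia": _icosphere((0, 0, -75), (34, 28, 60), 2, "tibia"),
        "patella": _icosphere((0, 30, 15), (13, 7, 16), 2, "patella"),
    }

    # Patella center radially outside its cartilage patch (phi ~ 30 deg).
    r_pc = p.trochlea_radius + p.patellar_gap + 6.0
    patella_center = np.array(
        [0.0, r_pc * np.cos(np.deg2rad(30.0)), r_pc * np.sin(np.deg2rad(30.0))]
    )
    tendon_origin = np.array([0.0, patella_center[1] + 1.0, patella_center[2] - 11.0])
    tendon_insertion = np.array([0.0, 22.0, -38.0])
    joint = JointDefinition(
        center=(0.0, 0.0, 0.0),
        patella_center=patella_center,
        tendon_origin_patella=tendon_origin,
        tendon_insertion_tibia=tendon_insertion,
        tendon_reference_length=float(
            np.linalg.norm(tendon_origin - tendon_insertion)
        ),
    )

    bundles = []
    for b in default_bundle_table():
        ob, op, ib, ip = _LIGAMENT_ATTACHMENTS[b.name]
        bundles.append(
            replace(
                b,
                origin_body=ob,
                origin_point=np.asarray(op, float),
                insertion_body=ib,
                insertion_point=np.asarray(ip, float),
            )
        )

    muscles = [
        MuscleUnit(
            name=name,
            vol0=vol,
            lf0=lf,
            path=[(ob, np.asarray(op, float)), (ib, np.asarray(ip, float))],
        )
        for name, vol, lf, ob, op, ib, ip in _MUSCLE_TABLE
    ]

    femur_markers = MarkerModel(
        names=["FME", "FLE", "FTH1", "FTH2"],
        local_positions=[(45, 0, 5), (-45, 0, 5), (-50, 35, 200), (40, 42, 180)],
    )
    tibia_markers = MarkerModel(
        names=["TMC", "TLC", "TMM", "TLM"],
        local_positions=[(40, 8, -20), (-40, 8, -20), (25, 0, -380), (-28, -5, -375)],
    )
    return KneeGeometry(
        params=p,
        surfaces=surfaces,
        bones=bones,
        joint=joint,
        ligament_bundles=bundles,
        muscles=muscles,
        femur_markers=femur_markers,
        tibia_markers=tibia_markers,
    )


# ---------------------------------------------------------------------------
# Activity profiles
# ---------------------------------------------------------------------------


@dataclass
class ActivityParams:
    """Waveform and sampling parameters of one synthetic trial."""

    duration_s: float | None = None
    marker_rate_hz: float = 100.0
    grf_rate_hz: float = 1000.0
    noise_sigma_mm: float = 1.0
    subject_mass_kg: float = 73.4
    subject_height_m: float = 1.78
    shank_foot_mass_fraction: float = 0.061
    ankle_height_mm: float = -430.0  # floor level relative to the knee center
    adduction_moment_scale: float = 1.0


_DEFAULT_DURATIONS = {
    "walk": 1.0,
    "stair_ascent": 1.4,
    "stair_descent": 1.4,
    "sit_to_stand": 1.6,
    "stand_to_sit": 1.6,
}


def _bump(p, c, w):
    return np.exp(-(((p - c) / w) ** 2))


def _bump_per(p, c, w):
    return sum(_bump(p, c + k, w) for k in (-100.0, 0.0, 100.0))


def _logistic(p, c, w):
    return 1.0 / (1.0 + np.exp(-(p - c) / w))


def _smooth_window(p, lo, hi, ramp):
    up = np.clip((p - lo) / ramp, 0.0, 1.0)
    down = np.clip((hi - p) / ramp, 0.0, 1.0)
    w = np.minimum(up, down)
    return 0.5 - 0.5 * np.cos(np.pi * w)


def flexion_waveform(activity: str, percent: np.ndarray) -> np.ndarray:
    """Ground-truth knee flexion (deg) over 0-100% cycle."""
    p = percent
    if activity == "walk":
        return 4.0 + 14.0 * _bump_per(p, 15.0, 7.0) + 56.0 * _bump_per(p, 72.0, 9.5)
    if activity == "stair_ascent":
        return 8.0 + 54.0 * _bump_per(p, 2.0, 16.0) + 86.0 * _bump_per(p, 76.0, 11.0)
    if activity == "stair_descent":
        return (
            12.0 + 24.0 * _bump_per(p, 20.0, 12.0) + 78.0 * _bump_per(p, 78.0, 12.0)
        )
    if activity == "sit_to_stand":
        return 3.0 + 85.0 * (1.0 - _logistic(p, 45.0, 11.0))
    if activity == "stand_to_sit":
        return 3.0 + 85.0 * _logistic(p, 55.0, 11.0)
    raise ValueError(f"unknown activity {activity!r}")


def grf_waveform(activity: str, percent: np.ndarray, bw: float) -> np.ndarray:
    """Vertical/AP/ML ground reaction force (N) on the instrumented foot.

    For gait activities the stance window is 0-62% and the walking
    amplitude is rescaled so the two-feet vertical impulse over the cycle
    equals body weight times cycle duration.
    """
    p = percent
    out = np.zeros((len(p), 3))
    if activity == "walk":
        win = _smooth_window(p, 0.0, 62.0, 5.0)
        fz = (
            0.80 * _bump(p, 13.0, 9.0)
            + 0.75 * _bump(p, 50.0, 9.0)
            + 0.30 * _bump(p, 31.0, 14.0)
        ) * win
        both = fz + np.interp((p + 50.0) % 100.0, p, fz)
        fz *= 1.0 / both.mean()
        fy = (-0.16 * _bump(p, 12.0, 6.0) + 0.18 * _bump(p, 52.0, 6.0)) * win
        fx = 0.04 * _bump(p, 30.0, 18.0) * win
    elif activity in ("stair_ascent", "stair_descent"):
        win = _smooth_window(p, 0.0, 64.0, 6.0)
        first = 1.05 if activity == "stair_ascent" else 0.85
        second = 0.85 if activity == "stair_ascent" else 1.10
        fz = (
            first * _bump(p, 16.0, 10.0)
            + second * _bump(p, 48.0, 10.0)
            + 0.35 * _bump(p, 32.0, 14.0)
        ) * win
        fy = (-0.10 * _bump(p, 14.0, 7.0) + 0.12 * _bump(p, 50.0, 7.0)) * win
        fx = 0.05 * _bump(p, 32.0, 18.0) * win
    elif activity == "sit_to_stand":
        fz = 0.16 + 0.30 * _logistic(p, 25.0, 6.0) + 0.10 * _bump(p, 35.0, 12.0)
        fy = 0.03 * _bump(p, 30.0, 15.0)
        fx = np.zeros_like(p)
    elif activity == "stand_to_sit":
        fz = 0.16 + 0.30 * (1.0 - _logistic(p, 75.0, 6.0)) + 0.10 * _bump(
            p, 65.0, 12.0
        )
        fy = -0.03 * _bump(p, 70.0, 15.0)
        fx = np.zeros_like(p)
    else:
        raise ValueError(f"unknown activity {activity!r}")
    out[:, 0] = fx * bw
    out[:, 1] = fy * bw
    out[:, 2] = fz * bw
    return out


def knee_moment_targets(
    activity: str, percent: np.ndarray, bw: float, adduction_scale: float = 1.0
) -> np.ndarray:
    """External knee moment targets (N*mm, tibia frame) realized via COP.

    x: flexion demand (positive recruits extensors), y: ab/adduction
    loading that shifts compartment load, z: kept zero via the free moment.
    """
    p = percent
    m = np.zeros((len(p), 3))
    if activity == "walk":
        mx = 28.0 * _bump(p, 15.0, 8.0) - 12.0 * _bump(p, 42.0, 10.0) + 22.0 * _bump(
            p, 52.0, 7.0
        )
        my = -24.0 * (_bump(p, 14.0, 9.0) + 0.9 * _bump(p, 48.0, 9.0))
    elif activity == "stair_ascent":
        mx = 44.0 * _bump(p, 16.0, 10.0) + 18.0 * _bump(p, 48.0, 10.0)
        my = -26.0 * (_bump(p, 16.0, 10.0) + 0.8 * _bump(p, 48.0, 10.0))
    elif activity == "stair_descent":
        mx = 28.0 * _bump(p, 16.0, 10.0) + 44.0 * _bump(p, 48.0, 10.0)
        my = -28.0 * (0.8 * _bump(p, 16.0, 10.0) + _bump(p, 48.0, 10.0))
    elif activity == "sit_to_stand":
        mx = 72.0 * _bump(p, 30.0, 13.0)
        my = -14.0 * _bump(p, 30.0, 16.0)
    elif activity == "stand_to_sit":
        mx = 62.0 * _bump(p, 68.0, 13.0)
        my = -13.0 * _bump(p, 68.0, 16.0)
    else:
        raise ValueError(f"unknown activity {activity!r}")
    m[:, 0] = mx * bw  # lever arms in mm -> N*mm
    m[:, 1] = my * bw * adduction_scale
    return m


@dataclass
class ActivityTrial:
    """One generated activity cycle: drive signals, raw streams, markers."""

    activity: str
    params: ActivityParams
    seed: int
    trial: Trial  # external load per marker frame, tibia frame
    flexion_truth_deg: np.ndarray
    marker_times: np.ndarray
    marker_names: list[str]
    marker_positions: np.ndarray  # (n_frames, n_markers, 3), lab frame
    femur_poses: list[Pose]
    grf_times: np.ndarray
    grf_force: np.ndarray
    grf_cop: np.ndarray
    grf_free_moment: np.ndarray

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with io.StringIO() as buf:
            buf.write("time_s marker x_mm y_mm z_mm\n")
            for t, frame in zip(self.marker_times, self.marker_positions):
                for name, pos in zip(self.marker_names, frame):
                    buf.write(
                        f"{t:.4f} {name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n"
                    )
            (outdir / f"{self.activity}_markers.txt").write_text(buf.getvalue())
        with io.StringIO() as buf:
            buf.write("time_s fx_n fy_n fz_n copx_mm copy_mm free_mz_nmm\n")
            for t, f, c, mz in zip(
                self.grf_times, self.grf_force, self.grf_cop, self.grf_free_moment
            ):
                buf.write(
                    f"{t:.4f} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f} "
                    f"{c[0]:.6f} {c[1]:.6f} {mz[2]:.6f}\n"
                )
            (outdir / f"{self.activity}_grf.txt").write_text(buf.getvalue())
        with io.StringIO() as buf:
            buf.write("time_s flexion_deg\n")
            for t, th in zip(self.marker_times, self.flexion_truth_deg):
                buf.write(f"{t:.4f} {th:.6f}\n")
            (outdir / f"{self.activity}_flexion.txt").write_text(buf.getvalue())


def make_activity_trial(
    activity: str,
    geometry: KneeGeometry,
    params: ActivityParams | None = None,
    seed: int = 0,
) -> ActivityTrial:
    """Generate a seeded synthetic trial for one of the five activities.

    The ground-truth kinematics place the tibia at the laboratory origin;
    the femur flexes above it following the activity's flexion waveform.
    GRF center-of-pressure paths are inverse-designed so the quasi-static
    intersegmental load reproduces the activity's knee moment targets
    during foot contact.  Marker noise is isotropic Gaussian.
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}; expected one of {ACTIVITIES}")
    ap = params or ActivityParams()
    duration = ap.duration_s or _DEFAULT_DURATIONS[activity]
    bw = ap.subject_mass_kg * 9.81
    rng = np.random.default_rng(seed)

    n_m = int(round(duration * ap.marker_rate_hz)) + 1
    t_m = np.arange(n_m) / ap.marker_rate_hz
    n_g = int(round(duration * ap.grf_rate_hz)) + 1
    t_g = np.arange(n_g) / ap.grf_rate_hz
    p_m = 100.0 * t_m / duration
    p_g = 100.0 * t_g / duration

    flexion = flexion_waveform(activity, p_m)
    grf = grf_waveform(activity, p_g, bw)
    targets = knee_moment_targets(activity, p_g, bw, ap.adduction_moment_scale)

    # COP inverse design: applied moment about the knee from the platform is
    # cross(cop, F); choose cop (and the free moment about z) to meet the
    # targets wherever the vertical load is meaningful.
    h = ap.ankle_height_mm
    fz = grf[:, 2]
    loaded = fz > 0.02 * bw
    cop = np.zeros((n_g, 3))
    cop[:, 2] = h
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_y = (targets[:, 0] + h * grf[:, 1]) / fz
        cop_x = (h * grf[:, 0] - targets[:, 1]) / fz
    cop[:, 0] = np.where(loaded, np.clip(cop_x, -200.0, 200.0), 0.0)
    cop[:, 1] = np.where(loaded, np.clip(cop_y, -250.0, 250.0), 0.0)
    free = np.zeros((n_g, 3))
    cross_z = cop[:, 0] * grf[:, 1] - cop[:, 1] * grf[:, 0]
    free[:, 2] = np.where(loaded, -cross_z, 0.0)

    # Quasi-static intersegmental load at marker rate (lab = tibia frame).
    grf_m = resample_to(t_g, grf, t_m)
    cop_m = resample_to(t_g, cop, t_m)
    free_m = resample_to(t_g, free, t_m)
    com = np.tile(np.array([0.0, -5.0, -250.0]), (n_m, 1))
    knee_center = np.zeros((n_m, 3))
    f_knee, m_knee = intersegmental_load(
        t_m,
        knee_center,
        com,
        ap.shank_foot_mass_fraction * ap.subject_mass_kg,
        grf_m,
        cop_m,
        grf_free_moment=free_m,
        quasi_static=True,
    )
    trial = Trial(
        activity=activity,
        times=t_m,
        flexion_deg=flexion,
        external_force=-f_knee,
        external_moment=-m_knee,
    )

    # Virtual markers: tibia cluster static, femur cluster from the inverse
    # of the tibia-in-femur flexion pose.
    names = list(geometry.femur_markers.names) + list(geometry.tibia_markers.names)
    positions = np.empty((n_m, len(names), 3))
    femur_poses = []
    nf = len(geometry.femur_markers.names)
    for i, th in enumerate(flexion):
        tib_in_fem = tibia_pose_from_dofs(
            KneeDofState(tf_flexion=float(th)), geometry.joint
        )
        fem_in_lab = tib_in_fem.inverse()
        femur_poses.append(fem_in_lab)
        positions[i, :nf] = fem_in_lab.apply(geometry.femur_markers.local_positions)
        positions[i, nf:] = geometry.tibia_markers.local_positions
    positions += rng.normal(0.0, ap.noise_sigma_mm, size=positions.shape)

    return ActivityTrial(
        activity=activity,
        params=ap,
        seed=seed,
        trial=trial,
        flexion_truth_deg=flexion,
        marker_times=t_m,
        marker_names=names,
        marker_positions=positions,
        femur_poses=femur_poses,
        grf_times=t_g,
        grf_force=grf,
        grf_cop=cop,
        grf_free_moment=free,
    )


def flexion_from_markers(
    geometry: KneeGeometry,
    marker_names: list[str],
    marker_positions: np.ndarray,
) -> np.ndarray:
    """Marker-tracking stage: per-frame knee flexion from Kabsch pose fits."""
    fm, tm = geometry.femur_markers, geometry.tibia_markers
    out = np.empty(len(marker_positions))
    index = {n: i for i, n in enumerate(marker_names)}
    for i, frame in enumerate(marker_positions):
        obs_f = {n: frame[index[n]] for n in fm.names}
        obs_t = {n: frame[index[n]] for n in tm.names}
        pose_f, _ = pose_from_markers(fm, obs_f)
        pose_t, _ = pose_from_markers(tm, obs_t)
        out[i] = flexion_from_relative_pose(pose_f.inverse().compose(pose_t))
    return out


# ---------------------------------------------------------------------------
# Pseudo-reference curves (stand-in for external in vivo measurements)
# ---------------------------------------------------------------------------


def make_pseudo_reference(
    curve: Curve,
    amplitude: float = 0.0,
    phase_shift_percent: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Curve:
    """Distorted copy of a predicted curve for metric self-tests.

    ``reference = (1 + amplitude) * shift(curve) + noise``; the shift is
    circular in percent-cycle.  With zero noise, the Sprague-Geers metrics
    of (reference, curve) recover the imposed amplitude and phase.
    """
    pct = np.linspace(0.0, 100.0, N_CYCLE_POINTS)
    src = np.asarray(curve.values, float)
    shifted = np.interp((pct - phase_shift_percent) % 100.0, pct, src)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, N_CYCLE_POINTS) if noise_sigma > 0 else 0.0
    return Curve((1.0 + amplitude) * shifted + noise, curve.activity)
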