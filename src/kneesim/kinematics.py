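"""Rigid poses, marker-based pose fitting, and the 11-DOF knee joint.

Joint axes (right-handed, femur reference frame): x = flexion axis
(medial-lateral), y = anterior, z = superior.  Rotation order is intrinsic
flexion (x) -> abduction-adduction (y) -> internal-external (z).  Positive
flexion swings the tibia posteriorly (a rotation by -flexion about +x);
the remaining rotations follow the right-hand rule about their axes.
Translations are expressed along the fixed femur axes.  The
tibiofemoral joint keeps 1 driven + 5 secondary coordinates; the
patellofemoral joint keeps 5 coordinates, its superior-inferior translation
being eliminated by the rigid patellar tendon length constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from kneesim.errors import DomainError, UnderdeterminedError


@dataclass
class Pose:
    """Proper rigid transform ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "Pose":
        return cls(
            Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix(),
            translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """Pose equal to applying ``other`` first, then ``self``."""
        return Pose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def is_valid(self, tol: float = 1e-9) -> bool:
        r = self.rotation
        return (
            np.allclose(r.T @ r, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < 1e-6
        )


# ---------------------------------------------------------------------------
# Marker models and least-squares pose fitting (the MT stage)
# ---------------------------------------------------------------------------


@dataclass
class MarkerModel:
    """Body-fixed marker cluster: names, local positions (mm), weights."""

    names: list[str]
    local_positions: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.local_positions = np.asarray(self.local_positions, float).reshape(-1, 3)
        if len(self.names) != len(self.local_positions):
            raise ValueError("names/positions length mismatch")
        if self.weights is None:
            self.weights = np.ones(len(self.names))
        else:
            self.weights = np.asarray(self.weights, float).reshape(-1)
        _check_not_collinear(self.local_positions, self.weights)


def _check_not_collinear(points: np.ndarray, weights: np.ndarray) -> None:
    use = weights > 0
    pts = points[use]
    if len(pts) < 3:
        raise UnderdeterminedError("need at least 3 markers with positive weight")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(pts).max())) < 2:
        raise UnderdeterminedError("markers are collinear")


def pose_from_markers(
    model: MarkerModel, observed: np.ndarray | dict[str, np.ndarray]
) -> tuple[Pose, float]:
    """Weighted orthogonal-Procrustes (Kabsch) fit of a body pose.

    ``observed`` is either an array aligned with ``model.names`` or a dict
    keyed by marker name (missing markers get zero weight).  Returns the
    pose minimizing the weighted sum of squared marker distances and the
    weighted RMS residual in mm.
    """
    local = model.local_positions
    w = model.weights.copy()
    if isinstance(observed, dict):
        obs = np.zeros_like(local)
        for i, name in enumerate(model.names):
            if name in observed:
                obs[i] = np.asarray(observed[name], float)
            else:
                w[i] = 0.0
    else:
        obs = np.asarray(observed, float).reshape(-1, 3)
        if len(obs) != len(local):
            raise UnderdeterminedError("observed marker count mismatch")
    _check_not_collinear(local, w)
    wsum = w.sum()
    mu_l = (w[:, None] * local).sum(axis=0) / wsum
    mu_o = (w[:, None] * obs).sum(axis=0) / wsum
    H = (w[:, None] * (local - mu_l)).T @ (obs - mu_o)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_o - R @ mu_l
    pose = Pose(R, t)
    res = pose.apply(local) - obs
    rms = float(np.sqrt((w * np.einsum("ij,ij->i", res, res)).sum() / wsum))
    return pose, rms


# ---------------------------------------------------------------------------
# 11-DOF knee joint parameterization
# ---------------------------------------------------------------------------

#: Coordinate names of the 10 secondary DOFs, in solver order.  The
#: patella keeps 3 local rotations plus medial-lateral and radial
#: translations; its position along the trochlear arc (about the flexion
#: axis) is the coordinate eliminated by the rigid patellar tendon.
SECONDARY_NAMES = (
    "tf_abduction_deg",
    "tf_internal_rot_deg",
    "tf_ml_mm",
    "tf_ap_mm",
    "tf_si_mm",
    "pf_flexion_deg",
    "pf_spin_deg",
    "pf_tilt_deg",
    "pf_ml_mm",
    "pf_radial_mm",
)

#: True where the secondary coordinate is a rotation (residual in N*mm).
SECONDARY_IS_ROTATION = np.array(
    [True, True, False, False, False, True, True, True, False, False]
)


@dataclass
class KneeDofState:
    """1 driven + 10 secondary knee coordinates.

    ``tf_secondary`` = (abduction deg, internal rotation deg, ML mm, AP mm,
    SI mm) of the tibia relative to the femur; ``pf_secondary`` = (flexion,
    spin, tilt deg, ML mm, radial mm) of the patella relative to the femur.
    The patella's sixth coordinate — the arc angle about the flexion axis,
    i.e. its ride position along the trochlear groove — is eliminated by
    the rigid patellar tendon length constraint.
    """

    tf_flexion: float = 0.0
    tf_secondary: np.ndarray = field(default_factory=lambda: np.zeros(5))
    pf_secondary: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        self.tf_secondary = np.asarray(self.tf_secondary, float).reshape(5)
        self.pf_secondary = np.asarray(self.pf_secondary, float).reshape(5)

    @property
    def secondary(self) -> np.ndarray:
        return np.concatenate([self.tf_secondary, self.pf_secondary])

    @classmethod
    def from_secondary(cls, flexion: float, alpha: np.ndarray) -> "KneeDofState":
        alpha = np.asarray(alpha, float).reshape(10)
        return cls(flexion, alpha[:5].copy(), alpha[5:].copy())


@dataclass
class JointDefinition:
    """Geometric definition of the joint parameterization.

    All points in femur reference coordinates at the reference alignment.
    The flexion axis is the x-axis through ``center`` (fixture convention:
    the transepicondylar line).
    """

    center: np.ndarray
    patella_center: np.ndarray
    tendon_origin_patella: np.ndarray
    tendon_insertion_tibia: np.ndarray
    tendon_reference_length: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float).reshape(3)
        self.patella_center = np.asarray(self.patella_center, float).reshape(3)
        self.tendon_origin_patella = np.asarray(
            self.tendon_origin_patella, float
        ).reshape(3)
        self.tendon_insertion_tibia = np.asarray(
            self.tendon_insertion_tibia, float
        ).reshape(3)
        if self.tendon_reference_length <= 0:
            raise DomainError("tendon reference length must be positive")


def _euler_pose(angles_deg: np.ndarray, pivot: np.ndarray, d: np.ndarray) -> Pose:
    R = Rotation.from_euler("XYZ", angles_deg, degrees=True).as_matrix()
    return Pose(R, pivot + d - R @ pivot)


def tibia_pose_from_dofs(state: KneeDofState, jd: JointDefinition) -> Pose:
    angles = np.array(
        [-state.tf_flexion, state.tf_secondary[0], state.tf_secondary[1]]
    )
    return _euler_pose(angles, jd.center, state.tf_secondary[2:5])


def _patella_radial_dir(jd: JointDefinition) -> np.ndarray:
    """Unit radial direction of the patella center about the flexion axis."""
    v = jd.patella_center - jd.center
    r = np.hypot(v[1], v[2])
    if r < 1e-9:
        raise DomainError("patella center lies on the flexion axis")
    return np.array([0.0, v[1] / r, v[2] / r])


def _arc_pose(zeta_deg: float, jd: JointDefinition) -> Pose:
    """Rotation by ``zeta`` about the flexion axis through the joint center."""
    R = Rotation.from_euler("X", zeta_deg, degrees=True).as_matrix()
    return Pose(R, jd.center - R @ jd.center)


def patella_pose_from_dofs(
    state: KneeDofState, jd: JointDefinition, zeta_deg: float
) -> Pose:
    """Patella pose: local Euler rotations about the patella center plus
    ML/radial translations, pre-rotated by the arc angle ``zeta`` about the
    flexion axis (the tendon-eliminated coordinate)."""
    angles = state.pf_secondary[:3]
    rdir = _patella_radial_dir(jd)
    d = state.pf_secondary[3] * np.array([1.0, 0.0, 0.0]) + state.pf_secondary[4] * rdir
    local = _euler_pose(angles, jd.patella_center, d)
    return _arc_pose(zeta_deg, jd).compose(local)


def solve_tendon_arc(
    state: KneeDofState,
    jd: JointDefinition,
    tibia_pose: Pose,
    zeta_guess_deg: float = 0.0,
) -> float:
    """Arc angle (deg) at which the patellar tendon regains its rigid length.

    Closed form: the tendon origin rides a circle about the flexion axis,
    so ``|a(zeta) - b| = L`` reduces to ``cos(zeta + delta) = C``; of the
    two roots the one nearest ``zeta_guess_deg`` is returned, which keeps
    the branch continuous over a trial.  Out-of-reach configurations are
    clamped to the closest-approach angle.
    """
    b = tibia_pose.apply(jd.tendon_insertion_tibia) - jd.center
    local = _euler_pose(
        state.pf_secondary[:3],
        jd.patella_center,
        state.pf_secondary[3] * np.array([1.0, 0.0, 0.0])
        + state.pf_secondary[4] * _patella_radial_dir(jd),
    )
    a = local.apply(jd.tendon_origin_patella) - jd.center
    w = np.hypot(a[1], a[2])
    v = np.hypot(b[1], b[2])
    if w < 1e-9 or v < 1e-9:
        raise DomainError("tendon end lies on the flexion axis")
    num = w**2 + v**2 + (a[0] - b[0]) ** 2 - jd.tendon_reference_length**2
    cos_delta = np.clip(num / (2.0 * w * v), -1.0, 1.0)
    delta = np.degrees(np.arccos(cos_delta))
    base = np.degrees(np.arctan2(b[2], b[1]) - np.arctan2(a[2], a[1]))
    candidates = []
    for root in (base + delta, base - delta):
        # Fold into the turn nearest the guess.
        k = np.round((zeta_guess_deg - root) / 360.0)
        candidates.append(root + 360.0 * k)
    return float(min(candidates, key=lambda z: abs(z - zeta_guess_deg)))


def knee_pose_from_dofs(
    state: KneeDofState,
    jd: JointDefinition,
    enforce_tendon: bool = True,
    zeta_deg: float = 0.0,
) -> tuple[Pose, Pose, float]:
    """Poses of tibia and patella relative to the femur.

    With ``enforce_tendon`` the patellar arc angle is resolved from the
    rigid tendon constraint (``zeta_deg`` then selects the nearest branch).
    Returns (tibia pose, patella pose, resolved arc angle deg).
    """
    tp = tibia_pose_from_dofs(state, jd)
    zeta = (
        solve_tendon_arc(state, jd, tp, zeta_deg) if enforce_tendon else float(zeta_deg)
    )
    return tp, patella_pose_from_dofs(state, jd, zeta), zeta


def dofs_from_poses(
    tibia_pose: Pose, patella_pose: Pose, jd: JointDefinition
) -> tuple[KneeDofState, float]:
    """Inverse parameterization (exact away from gimbal lock).

    Returns the state and the patellar arc angle ``zeta``.
    """
    ang_t = Rotation.from_matrix(tibia_pose.rotation).as_euler("XYZ", degrees=True)
    d_t = tibia_pose.translation - jd.center + tibia_pose.rotation @ jd.center
    # Patella: split off the arc rotation from the world center position.
    u0 = jd.patella_center - jd.center
    c_w = patella_pose.apply(jd.patella_center) - jd.center
    psi0 = np.arctan2(u0[2], u0[1])
    rho0 = np.hypot(u0[1], u0[2])
    zeta = np.degrees(
        (np.arctan2(c_w[2], c_w[1]) - psi0 + np.pi) % (2 * np.pi) - np.pi
    )
    dr = np.hypot(c_w[1], c_w[2]) - rho0
    ml = c_w[0] - u0[0]
    R_local = _arc_pose(zeta, jd).rotation.T @ patella_pose.rotation
    ang_p = Rotation.from_matrix(R_local).as_euler("XYZ", degrees=True)
    return (
        KneeDofState(
            tf_flexion=float(-ang_t[0]),
            tf_secondary=np.array([ang_t[1], ang_t[2], d_t[0], d_t[1], d_t[2]]),
            pf_secondary=np.array([ang_p[0], ang_p[1], ang_p[2], ml, dr]),
        ),
        float(zeta),
    )


def patellar_tendon_residual(
    tibia_pose: Pose, patella_pose: Pose, jd: JointDefinition
) -> float:
    """Current tendon length minus the rigid reference length (mm)."""
    a = patella_pose.apply(jd.tendon_origin_patella)
    b = tibia_pose.apply(jd.tendon_insertion_tibia)
    return float(np.linalg.norm(a - b)) - jd.tendon_reference_length


def flexion_from_relative_pose(pose: Pose) -> float:
    """Flexion angle (deg) extracted from a femur->tibia relative pose."""
    return float(
        -Rotation.from_matrix(pose.rotation).as_euler("XYZ", degrees=True)[0]
    )
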