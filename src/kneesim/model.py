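"""Knee model assembly and per-frame generalized force evaluation.

The femur is the ground body.  The tibia carries the driven flexion DOF and
5 secondary coordinates; the patella carries 5 coordinates with its
superior-inferior translation eliminated by the rigid patellar tendon.  All
surfaces, attachment points and muscle paths are stored in femur reference
coordinates at the full-extension reference alignment and move with their
bodies.

Generalized residual forces conjugate to the 10 secondary coordinates are
assembled from ligament bundles, elastic-foundation contact, recruited
muscle forces, the patellar tendon constraint force, and the external
intersegmental load.  The tendon tension is the constraint multiplier of
the eliminated patellar coordinate, so that coordinate's residual vanishes
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from kneesim.contact import ContactPair, ContactResult, PairContactEngine
from kneesim.errors import ConfigurationError
from kneesim.kinematics import (
    JointDefinition,
    KneeDofState,
    Pose,
    _patella_radial_dir,
    knee_pose_from_dofs,
)
from kneesim.ligaments import LigamentBundle, bundle_force, slack_length_from_reference
from kneesim.mesh import TriMesh
from kneesim.recruitment import (
    MuscleUnit,
    RecruitmentProblem,
    RecruitmentSolution,
    solve_recruitment,
)

FEMUR, TIBIA, PATELLA = "femur", "tibia", "patella"
_BODY_CODE = {FEMUR: 0, TIBIA: 1, PATELLA: 2}


@dataclass
class FrameInputs:
    """External drive for one simulation frame.

    ``flexion_deg`` drives the tibiofemoral flexion DOF; the external
    intersegmental load (N, N*mm about the knee center) is expressed in the
    tibia anatomical frame.
    """

    time: float
    flexion_deg: float
    external_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    external_moment: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.external_force = np.asarray(self.external_force, float).reshape(3)
        self.external_moment = np.asarray(self.external_moment, float).reshape(3)


@dataclass
class FrameForces:
    """Full force state evaluated at one pose (diagnostics + TFCF source)."""

    residual: np.ndarray
    contact_results: list[ContactResult]
    pair_compartments: list[str]
    ligament_forces: np.ndarray
    recruitment: RecruitmentSolution | None
    muscle_forces: np.ndarray
    tendon_tension: float
    tibia_pose: Pose
    patella_pose: Pose
    pf_zeta_deg: float

    def tfcf_vectors(self) -> dict[str, np.ndarray]:
        """Tibiofemoral contact resultants on the tibia by compartment (N)."""
        med = np.zeros(3)
        lat = np.zeros(3)
        for res, comp in zip(self.contact_results, self.pair_compartments):
            if comp == "medial":
                med += res.resultant_on_slave()
            elif comp == "lateral":
                lat += res.resultant_on_slave()
        return {"medial": med, "lateral": lat, "total": med + lat}


class KneeModel:
    """Assembled knee construct bound to geometry, ligaments and muscles."""

    def __init__(
        self,
        joint: JointDefinition,
        pairs: list[ContactPair],
        pair_bodies: list[str],
        pair_compartments: list[str],
        ligament_bundles: list[LigamentBundle],
        muscles: list[MuscleUnit],
        subject_mass_kg: float,
        moment_lever_mm: float = 10.0,
        surfaces: dict[str, TriMesh] | None = None,
    ):
        self.joint = joint
        self.pairs = pairs
        self.pair_bodies = list(pair_bodies)
        self.pair_compartments = list(pair_compartments)
        self.engines = [PairContactEngine(p) for p in pairs]
        self.muscles = muscles
        self.subject_mass_kg = float(subject_mass_kg)
        self.moment_lever_mm = float(moment_lever_mm)
        self.surfaces = surfaces or {}
        self.ligaments = ligament_bundles
        self._prepare_ligaments()
        self._prepare_muscles()
        self._zeta_guess = 0.0

    @property
    def body_weight_n(self) -> float:
        return self.subject_mass_kg * 9.81

    # -- assembly --------------------------------------------------------

    def _prepare_ligaments(self) -> None:
        for b in self.ligaments:
            if b.origin_point is None or b.insertion_point is None:
                raise ConfigurationError(f"ligament {b.name} lacks attachment points")
        self._lig_o_body = np.array(
            [_BODY_CODE[b.origin_body] for b in self.ligaments]
        )
        self._lig_i_body = np.array(
            [_BODY_CODE[b.insertion_body] for b in self.ligaments]
        )
        self._lig_o_pts = np.array([b.origin_point for b in self.ligaments])
        self._lig_i_pts = np.array([b.insertion_point for b in self.ligaments])
        self._lig_k = np.array([b.k for b in self.ligaments])
        self._lig_eps_l = np.array([b.eps_l for b in self.ligaments])
        ref_len = np.linalg.norm(self._lig_o_pts - self._lig_i_pts, axis=1)
        for b, L in zip(self.ligaments, ref_len):
            if not np.isfinite(b.L0):
                b.L0 = slack_length_from_reference(float(L), b.eps_r)
        self._lig_L0 = np.array([b.L0 for b in self.ligaments])

    def _prepare_muscles(self) -> None:
        for m in self.muscles:
            if len(m.path) < 2:
                raise ConfigurationError(f"muscle {m.name} path too short")
        self._mus_N = np.array([m.n_i for m in self.muscles])
        self._mus_V = np.array([m.v_i for m in self.muscles])

    # -- kinematics helpers ----------------------------------------------

    def poses(self, state: KneeDofState) -> tuple[Pose, Pose, float]:
        tp, pp, zeta = knee_pose_from_dofs(state, self.joint, zeta_deg=self._zeta_guess)
        self._zeta_guess = zeta
        return tp, pp, zeta

    def _body_poses(self, tp: Pose, pp: Pose) -> list[Pose]:
        return [Pose.identity(), tp, pp]

    def _muscle_lengths(self, state: KneeDofState, zeta_guess: float) -> np.ndarray:
        tp, pp, _ = knee_pose_from_dofs(state, self.joint, zeta_deg=zeta_guess)
        poses = self._body_poses(tp, pp)
        out = np.empty(len(self.muscles))
        for i, m in enumerate(self.muscles):
            pts = np.array([poses[_BODY_CODE[b]].apply(p) for b, p in m.path])
            out[i] = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        return out

    def flexion_moment_arms(
        self, state: KneeDofState, zeta_guess: float, h_deg: float = 0.05
    ) -> np.ndarray:
        """Tendon-excursion moment coefficients about the flexion DOF.

        ``-dL/d(theta)`` per muscle (N*mm per N), central differences; the
        patellar tendon elimination is re-solved at each perturbed flexion,
        so quadriceps transmission through the patella is included.
        """
        sp = KneeDofState(state.tf_flexion + h_deg, state.tf_secondary, state.pf_secondary)
        sm = KneeDofState(state.tf_flexion - h_deg, state.tf_secondary, state.pf_secondary)
        dl = self._muscle_lengths(sp, zeta_guess) - self._muscle_lengths(sm, zeta_guess)
        return -dl / (2.0 * np.deg2rad(h_deg))

    # -- generalized force bookkeeping ------------------------------------

    @staticmethod
    def _rotation_axes(angles_deg: np.ndarray) -> np.ndarray:
        """Instantaneous axes of the intrinsic X-Y-Z coordinates."""
        rx = Rotation.from_euler("X", angles_deg[0], degrees=True).as_matrix()
        rxy = rx @ Rotation.from_euler("Y", angles_deg[1], degrees=True).as_matrix()
        return np.array([[1.0, 0.0, 0.0], rx[:, 1], rxy[:, 2]])

    def evaluate(
        self, alpha: np.ndarray, frame: FrameInputs, with_muscles: bool = True
    ) -> FrameForces:
        """Assemble all forces and the 10 secondary generalized residuals."""
        state = KneeDofState.from_secondary(frame.flexion_deg, alpha)
        tp, pp, zeta = self.poses(state)
        poses = self._body_poses(tp, pp)

        # Wrench accumulators: force and moment about each body's pivot.
        o_t = self.joint.center + state.tf_secondary[2:5]
        o_p = pp.apply(self.joint.patella_center)
        F = {TIBIA: np.zeros(3), PATELLA: np.zeros(3)}
        M = {TIBIA: np.zeros(3), PATELLA: np.zeros(3)}
        pivots = {TIBIA: o_t, PATELLA: o_p}

        def add_force(body: str, point: np.ndarray, force: np.ndarray) -> None:
            F[body] += force
            M[body] += np.cross(point - pivots[body], force)

        # Ligaments.
        o_world = np.array(
            [poses[c].apply(p) for c, p in zip(self._lig_o_body, self._lig_o_pts)]
        )
        i_world = np.array(
            [poses[c].apply(p) for c, p in zip(self._lig_i_body, self._lig_i_pts)]
        )
        diff = o_world - i_world
        lengths = np.linalg.norm(diff, axis=1)
        eps = (lengths - self._lig_L0) / self._lig_L0
        lig_f = np.asarray(bundle_force(eps, self._lig_k, self._lig_eps_l))
        unit = diff / lengths[:, None]
        for j in range(len(self.ligaments)):
            if lig_f[j] <= 0.0:
                continue
            fo = lig_f[j] * unit[j]
            for code, pt, fvec in (
                (self._lig_i_body[j], i_world[j], fo),
                (self._lig_o_body[j], o_world[j], -fo),
            ):
                if code == 1:
                    add_force(TIBIA, pt, fvec)
                elif code == 2:
                    add_force(PATELLA, pt, fvec)

        # Contact (master = femur at identity).
        contact_results = []
        for pair, engine, body in zip(self.pairs, self.engines, self.pair_bodies):
            pose_slave = tp if body == TIBIA else pp
            depths, pts, normals = engine.depths(pose_slave, Pose.identity())
            forces = pair.pm * engine.areas * depths
            res = ContactResult(
                pair_name=pair.name,
                points=pts,
                depths=depths,
                areas=engine.areas,
                forces=forces,
                directions=-normals,
                compartments=engine.vertex_comp,
            )
            contact_results.append(res)
            active = depths > 0
            if active.any():
                vecs = res.force_vectors()[active]
                F[body] += vecs.sum(axis=0)
                M[body] += np.cross(pts[active] - pivots[body], vecs).sum(axis=0)

        # External intersegmental load at the knee center, tibia frame.
        knee_pt = tp.apply(self.joint.center)
        ext_f = tp.rotation @ frame.external_force
        ext_m = tp.rotation @ frame.external_moment
        add_force(TIBIA, knee_pt, ext_f)
        M[TIBIA] += ext_m

        # Tendon geometry.
        a = pp.apply(self.joint.tendon_origin_patella)
        b = tp.apply(self.joint.tendon_insertion_tibia)
        u = a - b
        u /= np.linalg.norm(u)

        def tendon_tension() -> float:
            """Constraint multiplier zeroing the eliminated arc coordinate."""
            m_cj = M[PATELLA] + np.cross(o_p - self.joint.center, F[PATELLA])
            coef = np.cross(a - self.joint.center, u)[0]
            return float(m_cj[0] / coef)

        # Euler angles of the tibia rotation (flexion enters negated).
        axes_t = self._rotation_axes(
            np.array([-state.tf_flexion, *state.tf_secondary[:2]])
        )
        flex_axis = -axes_t[0]  # conjugate axis of the flexion coordinate

        # Muscle recruitment on the driven flexion equation.
        recruitment_solution = None
        mus_f = np.zeros(len(self.muscles))
        if with_muscles and self.muscles:
            t0 = tendon_tension()
            q_flex = flex_axis @ (
                M[TIBIA] + np.cross(b - pivots[TIBIA], t0 * u)
            )
            arms = self.flexion_moment_arms(state, zeta)
            problem = RecruitmentProblem(
                C=arms[None, :],
                r=np.array([-q_flex]),
                is_muscle=np.ones(len(self.muscles), bool),
                N=self._mus_N,
                V=self._mus_V,
            )
            recruitment_solution = solve_recruitment(problem)
            mus_f = recruitment_solution.x
            for mf, m in zip(mus_f, self.muscles):
                if mf <= 0.0:
                    continue
                pts = np.array([poses[_BODY_CODE[bd]].apply(p) for bd, p in m.path])
                # Pull at each end point toward its neighbour.
                for end, nbr, (bd, _) in (
                    (pts[-1], pts[-2], m.path[-1]),
                    (pts[0], pts[1], m.path[0]),
                ):
                    if bd == FEMUR:
                        continue
                    d = nbr - end
                    fvec = mf * d / np.linalg.norm(d)
                    add_force(TIBIA if bd == TIBIA else PATELLA, end, fvec)

        # Patellar tendon tension: multiplier of the eliminated arc coordinate.
        tension = tendon_tension()
        add_force(PATELLA, a, -tension * u)
        add_force(TIBIA, b, tension * u)

        arc = Rotation.from_euler("X", zeta, degrees=True).as_matrix()
        axes_p = self._rotation_axes(state.pf_secondary[:3]) @ arc.T
        rdir_world = arc @ _patella_radial_dir(self.joint)
        residual = np.array(
            [
                axes_t[1] @ M[TIBIA],
                axes_t[2] @ M[TIBIA],
                F[TIBIA][0],
                F[TIBIA][1],
                F[TIBIA][2],
                axes_p[0] @ M[PATELLA],
                axes_p[1] @ M[PATELLA],
                axes_p[2] @ M[PATELLA],
                F[PATELLA][0],
                F[PATELLA] @ rdir_world,
            ]
        )
        return FrameForces(
            residual=residual,
            contact_results=contact_results,
            pair_compartments=self.pair_compartments,
            ligament_forces=lig_f,
            recruitment=recruitment_solution,
            muscle_forces=mus_f,
            tendon_tension=float(tension),
            tibia_pose=tp,
            patella_pose=pp,
            pf_zeta_deg=zeta,
        )

    def fdk_residual(self, alpha: np.ndarray, frame: FrameInputs) -> np.ndarray:
        """10-vector of generalized forces conjugate to the secondary DOFs.

        Rotational components in N*mm, translational in N, ordered as
        :data:`kneesim.kinematics.SECONDARY_NAMES`.
        """
        return self.evaluate(np.asarray(alpha, float), frame).residual
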