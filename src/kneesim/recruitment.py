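"""Muscle strength, cubic-polynomial recruitment, and intersegmental loads.

Recruitment minimizes ``sum_i V_i (f_i/N_i)^3`` over non-negative muscle
forces subject to the linear equilibrium system ``C f = r``; reaction and
residual unknowns are unbounded and carry no objective weight.  Ligament and
contact forces are position-dependent applied loads and enter through ``r``,
not as free unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from kneesim.errors import (
    AlignmentError,
    DomainError,
    GeometryError,
    InfeasibleError,
    RankError,
)

#: Default physiological cross-section strength factor (N/cm^2).
DEFAULT_MU = 27.0

#: Standard gravity in mm/s^2 (consistent with mm/N/N*mm unit system).
GRAVITY_MM = 9810.0


def max_isometric_force(vol0: float, lf0: float, mu: float = DEFAULT_MU) -> float:
    """Maximum isometric force ``F0 = mu * Vol0 / Lf0`` (N).

    ``vol0`` in cm^3, ``lf0`` in cm, ``mu`` in N/cm^2 (default 27).
    """
    if vol0 <= 0 or lf0 <= 0 or mu <= 0:
        raise DomainError("muscle volume, fiber length and mu must be positive")
    return mu * vol0 / lf0


@dataclass
class MuscleUnit:
    """A muscle-tendon unit: morphology, strength, and a polyline path.

    ``path`` lists (body name, local point mm) from origin over via points
    to insertion.  ``n_i`` defaults to ``f0`` (instantaneous strength equal
    to maximum isometric strength: no activation dynamics).
    """

    name: str
    vol0: float  # cm^3
    lf0: float  # cm
    mu: float = DEFAULT_MU
    v_i: float = 1.0
    path: list[tuple[str, np.ndarray]] = field(default_factory=list)
    n_i: float | None = None

    def __post_init__(self) -> None:
        self.f0 = max_isometric_force(self.vol0, self.lf0, self.mu)
        if self.n_i is None:
            self.n_i = self.f0
        if self.n_i <= 0 or self.v_i <= 0:
            raise DomainError(f"{self.name}: N_i and V_i must be positive")
        self.path = [(b, np.asarray(p, float).reshape(3)) for b, p in self.path]


@dataclass
class RecruitmentProblem:
    """Constraint system ``C x = r`` over muscles (bounded) and reactions (free)."""

    C: np.ndarray  # (m, n)
    r: np.ndarray  # (m,)
    is_muscle: np.ndarray  # (n,) bool; False entries are free reactions
    N: np.ndarray  # (n,) instantaneous strengths (ignored for reactions)
    V: np.ndarray  # (n,) volume weight factors (ignored for reactions)

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, float))
        self.r = np.asarray(self.r, float).reshape(-1)
        self.is_muscle = np.asarray(self.is_muscle, bool).reshape(-1)
        self.N = np.asarray(self.N, float).reshape(-1)
        self.V = np.asarray(self.V, float).reshape(-1)
        m, n = self.C.shape
        if len(self.r) != m or len(self.is_muscle) != n:
            raise ValueError("inconsistent problem dimensions")
        mus = self.is_muscle
        if np.any(self.N[mus] <= 0) or np.any(self.V[mus] <= 0):
            raise DomainError("muscle strengths and weights must be positive")
        dead = np.where(mus & (np.abs(self.C).sum(axis=0) == 0))[0]
        if len(dead):
            raise RankError(f"muscle columns {dead.tolist()} are identically zero")

    def objective(self, x: np.ndarray) -> float:
        f = x[self.is_muscle]
        return float(np.sum(self.V[self.is_muscle] * (f / self.N[self.is_muscle]) ** 3))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        mus = self.is_muscle
        g[mus] = 3.0 * self.V[mus] * x[mus] ** 2 / self.N[mus] ** 3
        return g


@dataclass
class RecruitmentSolution:
    x: np.ndarray  # all unknowns (muscles then/and reactions, problem order)
    objective: float
    constraint_residual: float
    kkt_residual: float
    status: str

    @property
    def forces(self) -> np.ndarray:
        return self.x


def _check_feasible(problem: RecruitmentProblem) -> np.ndarray:
    """Bounded least squares feasibility probe; returns a feasible start."""
    n = problem.C.shape[1]
    lb = np.where(problem.is_muscle, 0.0, -np.inf)
    res = optimize.lsq_linear(problem.C, problem.r, bounds=(lb, np.full(n, np.inf)))
    viol = problem.C @ res.x - problem.r
    tol = 1e-6 * max(1.0, float(np.linalg.norm(problem.r)))
    if np.linalg.norm(viol) > tol:
        worst = int(np.argmax(np.abs(viol)))
        raise InfeasibleError(
            f"equilibrium equation {worst} violated by {viol[worst]:.3g} "
            "(no non-negative muscle solution)",
            equation=worst,
        )
    return np.clip(res.x, np.where(problem.is_muscle, 0.0, -np.inf), np.inf)


def _solve_single_equation(problem: RecruitmentProblem) -> np.ndarray | None:
    """Closed-form KKT solution for one equality and no reactions.

    Stationarity gives ``f_i = N_i sqrt(lam c_i N_i / (3 V_i))`` on the
    active set ``sign(c_i) == sign(r)``; the common multiplier scales to
    meet the constraint.
    """
    if problem.C.shape[0] != 1 or not problem.is_muscle.all():
        return None
    c = problem.C[0]
    r = float(problem.r[0])
    x = np.zeros_like(c)
    if r == 0.0:
        return x
    active = np.sign(c) == np.sign(r)
    if not active.any():
        raise InfeasibleError(
            "equilibrium equation 0: no muscle can act in the required direction",
            equation=0,
        )
    Na, Va, ca = problem.N[active], problem.V[active], c[active]
    base = Na * np.sqrt(np.abs(ca) * Na / (3.0 * Va))  # f_i at sqrt(lam) = 1
    scale = r / float(ca @ base)  # equals sqrt(lam); > 0 by the sign selection
    x[active] = base * scale
    return x


def _kkt_residual(problem: RecruitmentProblem, x: np.ndarray) -> float:
    """Relative KKT stationarity residual via least-squares multipliers."""
    g = problem.gradient(x)
    nu, *_ = np.linalg.lstsq(problem.C.T, g, rcond=None)
    red = g - problem.C.T @ nu
    mus = problem.is_muscle
    at_bound = mus & (x <= 1e-9 * np.maximum(problem.N, 1.0))
    # At the bound only the one-sided condition (reduced gradient >= 0) binds.
    viol = np.where(at_bound, np.minimum(red, 0.0), red)
    scale = max(1.0, float(np.linalg.norm(g)))
    return float(np.linalg.norm(viol) / scale)


def solve_recruitment(
    problem: RecruitmentProblem, method: str = "auto"
) -> RecruitmentSolution:
    """Solve the cubic recruitment problem.

    ``method``: ``"auto"`` (closed form for single-equation all-muscle
    problems, otherwise SLSQP), ``"analytic"`` or ``"slsqp"``.
    """
    if method in ("auto", "analytic"):
        x = _solve_single_equation(problem)
        if x is not None:
            return _package(problem, x, "analytic")
        if method == "analytic":
            raise ValueError("analytic path needs 1 equation and no reactions")

    x0 = _check_feasible(problem)
    n = problem.C.shape[1]
    lb = np.where(problem.is_muscle, 0.0, -np.inf)
    res = optimize.minimize(
        problem.objective,
        x0,
        jac=problem.gradient,
        bounds=list(zip(lb, np.full(n, np.inf))),
        constraints=[{"type": "eq", "fun": lambda x: problem.C @ x - problem.r,
                      "jac": lambda x: problem.C}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = _polish(problem, res.x)
    return _package(problem, x, "slsqp")


def _polish(problem: RecruitmentProblem, x: np.ndarray, iters: int = 20) -> np.ndarray:
    """Newton refinement of the KKT system on the current active set."""
    mus = problem.is_muscle
    free = ~mus | (x > 1e-9 * np.maximum(problem.N, 1.0))
    if not free.any():
        return x
    idx = np.where(free)[0]
    C = problem.C[:, idx]
    m = len(problem.r)
    for _ in range(iters):
        g = problem.gradient(x)[idx]
        H = np.zeros(len(idx))
        H[mus[idx]] = 6.0 * problem.V[idx][mus[idx]] * x[idx][mus[idx]] / problem.N[
            idx
        ][mus[idx]] ** 3
        nu, *_ = np.linalg.lstsq(C.T, g, rcond=None)
        r1 = g - C.T @ nu
        r2 = problem.C @ x - problem.r
        if max(np.abs(r1).max(initial=0), np.abs(r2).max(initial=0)) < 1e-12:
            break
        KKT = np.block(
            [[np.diag(H), -C.T], [C, np.zeros((m, m))]]
        )
        try:
            step = np.linalg.lstsq(KKT, -np.concatenate([r1, r2]), rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        x_new = x.copy()
        x_new[idx] = x[idx] + step[: len(idx)]
        if np.any(x_new[idx][mus[idx]] < 0):
            break
        x = x_new
    return x


def _package(
    problem: RecruitmentProblem, x: np.ndarray, status: str
) -> RecruitmentSolution:
    x = np.where(problem.is_muscle & (np.abs(x) < 1e-12), 0.0, x)
    cres = float(np.linalg.norm(problem.C @ x - problem.r))
    return RecruitmentSolution(
        x=x,
        objective=problem.objective(x),
        constraint_residual=cres,
        kkt_residual=_kkt_residual(problem, x),
        status=status,
    )


# ---------------------------------------------------------------------------
# Moment arms and intersegmental loads
# ---------------------------------------------------------------------------


def moment_arm_matrix(
    muscle_world_paths: list[np.ndarray],
    joint_center: np.ndarray,
    axes: np.ndarray,
) -> np.ndarray:
    """Geometric moment coefficients (N*mm per N) about ``axes`` through
    ``joint_center``.

    Each muscle acts on the distal body at the last path point, directed
    toward the preceding point.  Rows are axes, columns muscles.
    """
    joint_center = np.asarray(joint_center, float)
    axes = np.atleast_2d(np.asarray(axes, float))
    cols = []
    for path in muscle_world_paths:
        path = np.asarray(path, float).reshape(-1, 3)
        if len(path) < 2:
            raise GeometryError("muscle path needs at least 2 points")
        seg = path[-2] - path[-1]
        length = np.linalg.norm(seg)
        if length < 1e-9:
            raise GeometryError("zero-length muscle path segment")
        u = seg / length
        cols.append(axes @ np.cross(path[-1] - joint_center, u))
    return np.column_stack(cols)


def resample_to(
    t_src: np.ndarray, values: np.ndarray, t_dst: np.ndarray
) -> np.ndarray:
    """Linear interpolation of a (n, k) series onto new timestamps."""
    values = np.atleast_2d(np.asarray(values, float).T).T
    return np.column_stack(
        [np.interp(t_dst, t_src, values[:, j]) for j in range(values.shape[1])]
    )


def intersegmental_load(
    times: np.ndarray,
    knee_center: np.ndarray,
    segment_com: np.ndarray,
    segment_mass: float,
    grf_force: np.ndarray,
    grf_cop: np.ndarray,
    grf_free_moment: np.ndarray | None = None,
    quasi_static: bool = True,
    gravity: float = GRAVITY_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Knee load carried by the femur on the shank+foot subsystem.

    Newton balance of the subsystem in lab coordinates (mm, N): returns
    per-frame force (N) and moment about the knee center (N*mm).  In
    dynamic mode the center-of-mass acceleration is estimated by central
    differences; rotary inertia is neglected (slender-segment reduction).
    All series must share the marker clock; resample the force-platform
    stream with :func:`resample_to` first.
    """
    times = np.asarray(times, float).reshape(-1)
    n = len(times)
    arrays = {
        "knee_center": np.asarray(knee_center, float).reshape(-1, 3),
        "segment_com": np.asarray(segment_com, float).reshape(-1, 3),
        "grf_force": np.asarray(grf_force, float).reshape(-1, 3),
        "grf_cop": np.asarray(grf_cop, float).reshape(-1, 3),
    }
    for name, arr in arrays.items():
        if len(arr) != n:
            raise AlignmentError(
                f"{name} has {len(arr)} frames, expected {n}: resample first"
            )
    g_vec = np.array([0.0, 0.0, -gravity])
    if quasi_static or n < 3:
        acc = np.zeros((n, 3))
    else:
        acc = np.gradient(
            np.gradient(arrays["segment_com"], times, axis=0), times, axis=0
        )
    # Force in N: masses in kg, accelerations mm/s^2 -> divide by 1000.
    inertial = segment_mass * (acc - g_vec) / 1000.0
    force = inertial - arrays["grf_force"]
    r_com = arrays["segment_com"] - arrays["knee_center"]
    r_cop = arrays["grf_cop"] - arrays["knee_center"]
    moment = np.cross(r_com, inertial) - np.cross(r_cop, arrays["grf_force"])
    if grf_free_moment is not None:
        moment -= np.asarray(grf_free_moment, float).reshape(-1, 3)
    return force, moment
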