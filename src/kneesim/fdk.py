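"""Force-dependent-kinematics solver and the trial simulation driver.

Per frame, the 10 secondary knee coordinates are searched until every
generalized residual force vanishes within threshold (1 N for force
components; 1 N times a characteristic lever, default 10 mm, for moment
components).  The search is a damped Newton iteration on the residual with
a central finite-difference Jacobian and Levenberg-style regularisation,
warm-started from the previous frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from kneesim.errors import InfeasibleError
from kneesim.kinematics import SECONDARY_IS_ROTATION
from kneesim.metrics import Curve, N_CYCLE_POINTS, normalize_cycle
from kneesim.model import FrameInputs, KneeModel

DEFAULT_THRESHOLD_N = 1.0
DEFAULT_MOMENT_LEVER_MM = 10.0
DEFAULT_MAX_ITER = 200
FD_STEP = 1e-3  # mm or deg


@dataclass
class FdkState:
    """Converged (or best-effort) secondary coordinates for one frame."""

    alpha: np.ndarray
    residual: np.ndarray
    iterations: int
    converged: bool

    def max_scaled_residual(self, scales: np.ndarray) -> float:
        return float(np.max(np.abs(self.residual) / scales))


def _residual_scales(
    n: int, is_rotation: np.ndarray | None, moment_lever: float
) -> np.ndarray:
    if is_rotation is None:
        is_rotation = np.zeros(n, dtype=bool)
    return np.where(np.asarray(is_rotation, bool), moment_lever, 1.0)


def fdk_residual(
    alpha: np.ndarray, frame_inputs: FrameInputs, model: KneeModel
) -> np.ndarray:
    """Generalized forces conjugate to the secondary coordinates."""
    return model.fdk_residual(alpha, frame_inputs)


def solve_fdk_frame(
    residual_fn: Callable[[np.ndarray], np.ndarray] | KneeModel,
    alpha0: np.ndarray,
    frame_inputs: FrameInputs | None = None,
    threshold: float = DEFAULT_THRESHOLD_N,
    moment_lever: float = DEFAULT_MOMENT_LEVER_MM,
    is_rotation: np.ndarray | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    fd_step: float = FD_STEP,
) -> FdkState:
    """Drive the secondary-coordinate residual below ``threshold``.

    ``residual_fn`` is either a plain callable ``alpha -> residual`` or a
    :class:`KneeModel` (then ``frame_inputs`` is required).  Moment
    components (per ``is_rotation``, defaulting to the knee layout for a
    10-vector) converge against ``threshold * moment_lever``.
    """
    if isinstance(residual_fn, KneeModel):
        model = residual_fn
        fn = lambda a: model.fdk_residual(a, frame_inputs)  # noqa: E731
        if is_rotation is None:
            is_rotation = SECONDARY_IS_ROTATION
    else:
        fn = residual_fn
    alpha = np.asarray(alpha0, float).copy()
    n = len(alpha)
    if is_rotation is None and n == len(SECONDARY_IS_ROTATION):
        is_rotation = SECONDARY_IS_ROTATION
    scales = _residual_scales(n, is_rotation, moment_lever)

    raw_fn = fn

    def try_fn(a: np.ndarray) -> np.ndarray | None:
        """Evaluate; infeasible recruitment at a trial pose rejects the step."""
        try:
            return np.asarray(raw_fn(a), float)
        except InfeasibleError:
            return None

    res = np.asarray(raw_fn(alpha), float)  # infeasible base pose propagates
    best = (alpha.copy(), res.copy())
    lam = 1e-3
    evals = 1
    for it in range(1, max_iter + 1):
        if np.max(np.abs(res) / scales) <= threshold:
            return FdkState(alpha, res, it - 1, True)
        J = _fd_jacobian(try_fn, alpha, res, fd_step)
        evals += 2 * n
        s = res / scales
        Js = J / scales[:, None]
        improved = False
        for _ in range(8):
            A = Js.T @ Js + lam * np.diag(np.maximum(np.diag(Js.T @ Js), 1e-8))
            try:
                step = np.linalg.solve(A, -Js.T @ s)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            # Trust-region style cap: no coordinate moves more than 2 units.
            mx = np.abs(step).max()
            if mx > 2.0:
                step *= 2.0 / mx
            trial = alpha + step
            res_t = try_fn(trial)
            evals += 1
            if res_t is not None and np.linalg.norm(res_t / scales) < np.linalg.norm(s):
                alpha, res = trial, res_t
                lam = max(lam / 3.0, 1e-6)
                improved = True
                break
            lam *= 10.0
        if not improved:
            # Fall back to a damped gradient step before giving up.
            g = Js.T @ s
            gn = np.linalg.norm(g)
            if gn < 1e-14:
                break
            t = 1.0
            for _ in range(10):
                trial = alpha - t * g / gn * min(1.0, np.linalg.norm(s))
                res_t = try_fn(trial)
                evals += 1
                if res_t is not None and np.linalg.norm(res_t / scales) < np.linalg.norm(s):
                    alpha, res = trial, res_t
                    improved = True
                    break
                t *= 0.5
            if not improved:
                break
        if np.linalg.norm(res / scales) < np.linalg.norm(best[1] / scales):
            best = (alpha.copy(), res.copy())
    if np.max(np.abs(res) / scales) <= threshold:
        return FdkState(alpha, res, max_iter, True)
    alpha, res = best if np.linalg.norm(best[1] / scales) < np.linalg.norm(
        res / scales
    ) else (alpha, res)
    return FdkState(alpha, res, max_iter, False)


def _fd_jacobian(
    fn: Callable[[np.ndarray], np.ndarray | None],
    alpha: np.ndarray,
    res0: np.ndarray,
    step: float,
) -> np.ndarray:
    """Central-difference Jacobian; falls back to one-sided differences
    when a perturbed pose cannot be evaluated."""
    J = np.empty((len(res0), len(alpha)))
    for j in range(len(alpha)):
        ap = alpha.copy()
        am = alpha.copy()
        ap[j] += step
        am[j] -= step
        rp = fn(ap)
        rm = fn(am)
        if rp is not None and rm is not None:
            J[:, j] = (rp - rm) / (2.0 * step)
        elif rp is not None:
            J[:, j] = (rp - res0) / step
        elif rm is not None:
            J[:, j] = (res0 - rm) / step
        else:
            J[:, j] = 0.0
    return J


def _ramp_in(
    model: KneeModel,
    trial: "Trial",
    threshold: float,
    lever: float,
    max_iter: int,
) -> np.ndarray:
    """Warm-start alpha for frame 0 by staging flexion up from extension.

    The first frame of a transfer activity starts near 90 degrees of
    flexion; solving unloaded intermediate flexion states walks the
    secondary coordinates (and the patellar arc branch) there continuously.
    """
    target = float(trial.flexion_deg[0])
    alpha = np.zeros(10)
    steps = max(2, int(np.ceil(abs(target - 4.0) / 12.0)))
    for th in np.linspace(4.0, target, steps + 1):
        state = solve_fdk_frame(
            model,
            alpha,
            frame_inputs=FrameInputs(time=-1.0, flexion_deg=float(th)),
            threshold=threshold,
            moment_lever=lever,
            max_iter=min(max_iter, 60),
        )
        alpha = state.alpha
    return alpha


# ---------------------------------------------------------------------------
# Trial driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationFrame:
    time: float
    flexion_deg: float
    state: FdkState
    tfcf_total_bw: float
    tfcf_medial_bw: float
    tfcf_lateral_bw: float
    tfcf_vectors_n: dict[str, np.ndarray]
    muscle_forces: np.ndarray
    tendon_tension: float
    ligament_forces: np.ndarray
    #: per contact pair: (compartment, force vector on the slave N, contacts)
    contact_rows: list[tuple[str, str, np.ndarray, int]] = field(
        default_factory=list
    )


@dataclass
class TrialResult:
    activity: str
    times: np.ndarray
    frames: list[SimulationFrame]
    curves: dict[str, Curve]
    failed_frames: list[int] = field(default_factory=list)

    @property
    def all_converged(self) -> bool:
        return not self.failed_frames

    def max_converged_residual(
        self, moment_lever: float = DEFAULT_MOMENT_LEVER_MM
    ) -> float:
        """Largest force-component residual magnitude over converged frames (N)."""
        force_mask = ~SECONDARY_IS_ROTATION
        vals = [
            np.abs(f.state.residual[force_mask]).max()
            for f in self.frames
            if f.state.converged
        ]
        return float(max(vals)) if vals else float("nan")

    def curve_table(self) -> "np.ndarray":
        pct = np.linspace(0.0, 100.0, N_CYCLE_POINTS)
        return np.column_stack(
            [
                pct,
                self.curves["total"].values,
                self.curves["medial"].values,
                self.curves["lateral"].values,
            ]
        )


@dataclass
class Trial:
    """Frame-by-frame drive signals for one activity cycle."""

    activity: str
    times: np.ndarray
    flexion_deg: np.ndarray
    external_force: np.ndarray  # (n,3) N, tibia frame
    external_moment: np.ndarray  # (n,3) N*mm, tibia frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float).reshape(-1)
        self.flexion_deg = np.asarray(self.flexion_deg, float).reshape(-1)
        self.external_force = np.asarray(self.external_force, float).reshape(-1, 3)
        self.external_moment = np.asarray(self.external_moment, float).reshape(-1, 3)

    def frame(self, i: int) -> FrameInputs:
        return FrameInputs(
            time=float(self.times[i]),
            flexion_deg=float(self.flexion_deg[i]),
            external_force=self.external_force[i],
            external_moment=self.external_moment[i],
        )


def run_trial(
    model: KneeModel,
    trial: Trial,
    threshold: float = DEFAULT_THRESHOLD_N,
    moment_lever: float | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha0: np.ndarray | None = None,
    progress: Callable[[int, FdkState], None] | None = None,
) -> TrialResult:
    """Simulate a full activity cycle and emit cycle-normalized TFCF curves.

    Frames are solved in order with warm starts; non-convergent frames are
    recorded in ``failed_frames`` and their best-effort state is kept so
    the output remains complete.
    """
    lever = moment_lever if moment_lever is not None else model.moment_lever_mm
    bw = model.body_weight_n
    n = len(trial.times)
    if alpha0 is None:
        alpha = _ramp_in(model, trial, threshold, lever, max_iter)
    else:
        alpha = np.asarray(alpha0, float).copy()
    frames: list[SimulationFrame] = []
    failed: list[int] = []
    for i in range(n):
        fi = trial.frame(i)
        state = solve_fdk_frame(
            model,
            alpha,
            frame_inputs=fi,
            threshold=threshold,
            moment_lever=lever,
            max_iter=max_iter,
        )
        if not state.converged:
            failed.append(i)
        alpha = state.alpha
        forces = model.evaluate(alpha, fi)
        vecs = forces.tfcf_vectors()
        contact_rows = [
            (res.pair_name, comp, res.resultant_on_slave(), res.n_contacting)
            for res, comp in zip(forces.contact_results, model.pair_compartments)
        ]
        frames.append(
            SimulationFrame(
                time=fi.time,
                flexion_deg=fi.flexion_deg,
                state=state,
                tfcf_total_bw=float(np.linalg.norm(vecs["total"]) / bw),
                tfcf_medial_bw=float(np.linalg.norm(vecs["medial"]) / bw),
                tfcf_lateral_bw=float(np.linalg.norm(vecs["lateral"]) / bw),
                tfcf_vectors_n=vecs,
                muscle_forces=forces.muscle_forces,
                tendon_tension=forces.tendon_tension,
                ligament_forces=forces.ligament_forces,
                contact_rows=contact_rows,
            )
        )
        if progress is not None:
            progress(i, state)
    curves = {
        key: normalize_cycle(
            trial.times,
            np.array([getattr(f, f"tfcf_{key}_bw") for f in frames]),
            activity=trial.activity,
        )
        for key in ("total", "medial", "lateral")
    }
    return TrialResult(
        activity=trial.activity,
        times=trial.times,
        frames=frames,
        curves=curves,
        failed_frames=failed,
    )


def write_curves(result: TrialResult, path) -> None:
    """Write the 101-point curve file (delimited text)."""
    table = result.curve_table()
    header = "activity,percent_cycle,tfcf_total_bw,tfcf_medial_bw,tfcf_lateral_bw"
    lines = [header]
    for row in table:
        lines.append(
            f"{result.activity},{row[0]:.1f},{row[1]:.9f},{row[2]:.9f},{row[3]:.9f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_contact_summary(result: TrialResult, path) -> None:
    """Per-frame, per-pair contact summary (delimited text):
    frame, pair, compartment, Fx, Fy, Fz, |F| (N), contacting vertices."""
    lines = ["frame,pair,compartment,fx_n,fy_n,fz_n,f_mag_n,n_contacting"]
    for i, f in enumerate(result.frames):
        for pair_name, comp, vec, count in f.contact_rows:
            lines.append(
                f"{i},{pair_name},{comp},{vec[0]:.6f},{vec[1]:.6f},"
                f"{vec[2]:.6f},{np.linalg.norm(vec):.6f},{count}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_frames(result: TrialResult, path) -> None:
    """Per-frame summary: time, flexion, convergence and compartment forces."""
    lines = [
        "time_s,flexion_deg,converged,iterations,max_force_residual_n,"
        "tfcf_total_bw,tfcf_medial_bw,tfcf_lateral_bw"
    ]
    force_mask = ~SECONDARY_IS_ROTATION
    for f in result.frames:
        lines.append(
            f"{f.time:.4f},{f.flexion_deg:.4f},{int(f.state.converged)},"
            f"{f.state.iterations},{np.abs(f.state.residual[force_mask]).max():.6f},"
            f"{f.tfcf_total_bw:.6f},{f.tfcf_medial_bw:.6f},{f.tfcf_lateral_bw:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
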