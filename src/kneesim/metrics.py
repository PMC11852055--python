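"""Cycle normalization and curve comparison metrics.

Curves are 101-point series on 0-100% normalized time, in body-weight
units.  Comparison metrics: RMSE, coefficient of determination, and the
Sprague-Geers magnitude/phase/combined errors computed from integral means
over the full window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kneesim.errors import DomainError

N_CYCLE_POINTS = 101

DOUBLE_PEAK_ACTIVITIES = ("walk", "stair_ascent", "stair_descent")
SINGLE_PEAK_ACTIVITIES = ("sit_to_stand", "stand_to_sit")
ACTIVITIES = DOUBLE_PEAK_ACTIVITIES + SINGLE_PEAK_ACTIVITIES


@dataclass
class Curve:
    """A cycle-normalized 101-sample curve (BW) with an activity label."""

    values: np.ndarray
    activity: str = "walk"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).reshape(-1)
        if len(self.values) != N_CYCLE_POINTS:
            raise ValueError(f"curve must have {N_CYCLE_POINTS} samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, N_CYCLE_POINTS)


@dataclass
class ComparisonMetrics:
    rmse: float
    r_squared: float
    sg_magnitude: float
    sg_phase: float
    c_e: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "sg_magnitude": self.sg_magnitude,
            "sg_phase": self.sg_phase,
            "c_e": self.c_e,
        }


@dataclass
class PeakSummary:
    """Peak values/locations and the cycle-mean medial load share."""

    first_peak: float
    first_peak_percent: float
    second_peak: float | None = None
    second_peak_percent: float | None = None
    medial_share_percent: float | None = None


def normalize_cycle(
    times: np.ndarray,
    values: np.ndarray,
    bounds: tuple[float, float] | None = None,
    activity: str = "walk",
) -> Curve:
    """Resample a time series onto 101 evenly spaced points in ``bounds``.

    Linear interpolation; window endpoints are preserved exactly when they
    coincide with samples.
    """
    times = np.asarray(times, float).reshape(-1)
    values = np.asarray(values, float).reshape(-1)
    if bounds is None:
        bounds = (float(times[0]), float(times[-1]))
    t0, t1 = bounds
    inside = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    if inside.sum() < 2 or not t1 > t0:
        raise DomainError("cycle window must contain at least 2 samples")
    grid = np.linspace(t0, t1, N_CYCLE_POINTS)
    return Curve(np.interp(grid, times, values), activity)


def _values(c) -> np.ndarray:
    return c.values if isinstance(c, Curve) else np.asarray(c, float).reshape(-1)


def rmse(c, m) -> float:
    """Root mean square error between computed ``c`` and measured ``m``."""
    cv, mv = _values(c), _values(m)
    if len(cv) != len(mv):
        raise ValueError("curves must have equal length")
    return float(np.sqrt(np.mean((cv - mv) ** 2)))


def r_squared(c, m) -> float:
    """Coefficient of determination of ``c`` against measured ``m``."""
    cv, mv = _values(c), _values(m)
    if len(cv) != len(mv):
        raise ValueError("curves must have equal length")
    ss_res = float(np.sum((cv - mv) ** 2))
    ss_tot = float(np.sum((mv - mv.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res == 0.0:
            return 1.0
        raise DomainError("R^2 undefined: measured curve is constant")
    return 1.0 - ss_res / ss_tot


def sprague_geers(c, m) -> tuple[float, float, float]:
    """Sprague-Geers magnitude M, phase P and combined error C_E.

    With integral means ``psi_ab = mean(a*b)``: ``M = sqrt(psi_cc/psi_mm)-1``,
    ``P = arccos(psi_cm / sqrt(psi_cc psi_mm)) / pi``, ``C_E = sqrt(M^2+P^2)``.
    """
    cv, mv = _values(c), _values(m)
    if len(cv) != len(mv):
        raise ValueError("curves must have equal length")
    psi_cc = float(np.mean(cv * cv))
    psi_mm = float(np.mean(mv * mv))
    psi_cm = float(np.mean(cv * mv))
    if psi_mm == 0.0:
        raise DomainError("Sprague-Geers undefined: measured curve has zero energy")
    magnitude = np.sqrt(psi_cc / psi_mm) - 1.0
    if psi_cc == 0.0:
        phase = 0.5  # orthogonal by convention when c is identically zero
    else:
        phase = np.arccos(np.clip(psi_cm / np.sqrt(psi_cc * psi_mm), -1.0, 1.0)) / np.pi
    return float(magnitude), float(phase), float(np.hypot(magnitude, phase))


def compare(c, m) -> ComparisonMetrics:
    """All curve comparison metrics in one structure."""
    mg, ph, ce = sprague_geers(c, m)
    return ComparisonMetrics(
        rmse=rmse(c, m), r_squared=r_squared(c, m), sg_magnitude=mg, sg_phase=ph, c_e=ce
    )


def extract_peaks(
    curve: Curve,
    activity: str | None = None,
    medial: Curve | None = None,
    total: Curve | None = None,
    split_percent: float = 50.0,
) -> PeakSummary:
    """Peak values/locations; two windows split at ``split_percent`` for
    double-peak activities, a single global maximum for transfers.

    Medial share (percent) is the ratio of cycle means when both ``medial``
    and ``total`` curves are supplied.
    """
    activity = activity or curve.activity
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    v = curve.values
    pct = curve.percent
    share = None
    if medial is not None and total is not None:
        share = 100.0 * float(np.mean(medial.values) / np.mean(total.values))
    if activity in DOUBLE_PEAK_ACTIVITIES:
        first = pct < split_percent
        i1 = int(np.argmax(v[first]))
        i2 = int(np.argmax(v[~first]))
        return PeakSummary(
            first_peak=float(v[first][i1]),
            first_peak_percent=float(pct[first][i1]),
            second_peak=float(v[~first][i2]),
            second_peak_percent=float(pct[~first][i2]),
            medial_share_percent=share,
        )
    i = int(np.argmax(v))
    return PeakSummary(
        first_peak=float(v[i]),
        first_peak_percent=float(pct[i]),
        medial_share_percent=share,
    )
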