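"""Bone-surface morphing: affine scaling, RBF warps, surface projection,
and length-mass-fat scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from kneesim.errors import (
    ConditioningError,
    DomainError,
    GeometryError,
    InvalidTransformError,
    PairingError,
)
from kneesim.mesh import TriMesh


@dataclass
class LandmarkSet:
    """Named 3D landmarks (mm); name order defines correspondence pairing."""

    names: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if len(self.names) != len(self.positions):
            raise ValueError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")

    def aligned_to(self, other: "LandmarkSet") -> np.ndarray:
        """Positions reordered to ``other``'s name order."""
        if set(self.names) != set(other.names):
            raise PairingError(
                "landmark name sets differ: "
                f"{sorted(set(self.names) ^ set(other.names))}"
            )
        index = {n: i for i, n in enumerate(self.names)}
        return self.positions[[index[n] for n in other.names]]

    @classmethod
    def from_file(cls, path: str | Path) -> "LandmarkSet":
        """Read delimited text rows ``name x y z`` (whitespace or comma)."""
        names, pos = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip().replace(",", " ")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        return cls(names, np.asarray(pos))

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{n} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            for n, p in zip(self.names, self.positions)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ScaleFactors:
    """Longitudinal/radial geometric factors and a muscle strength factor."""

    longitudinal: float
    radial: float
    strength: float

    def __post_init__(self) -> None:
        if min(self.longitudinal, self.radial, self.strength) <= 0:
            raise DomainError("scale factors must be strictly positive")


def affine_scale(
    mesh: TriMesh, linear: np.ndarray, translation: np.ndarray | None = None
) -> TriMesh:
    """Apply ``v -> linear @ v + translation`` to every vertex.

    Raises :class:`InvalidTransformError` for a singular linear map.
    """
    linear = np.asarray(linear, float).reshape(3, 3)
    if translation is None:
        translation = np.zeros(3)
    if abs(np.linalg.det(linear)) < 1e-12:
        raise InvalidTransformError("affine linear map is singular")
    return mesh.transformed(linear, np.asarray(translation, float))


def length_mass_fat_factors(
    subject_mass: float,
    subject_length: float,
    subject_fat: float,
    generic_mass: float,
    generic_length: float,
    generic_fat: float,
) -> ScaleFactors:
    """Length-mass-fat scaling convention for segment geometry and strength.

    The segment is treated as a fat-free-mass cylinder: the longitudinal
    factor is the length ratio; the radial factor preserves fat-free mass
    density; the strength factor scales maximum isometric force with
    fat-free mass per unit length.
    """
    vals = [subject_mass, subject_length, generic_mass, generic_length]
    if min(vals) <= 0:
        raise DomainError("masses and lengths must be positive")
    if not (0 <= subject_fat < 1 and 0 <= generic_fat < 1):
        raise DomainError("fat fractions must lie in [0, 1)")
    longitudinal = subject_length / generic_length
    ffm_ratio = (subject_mass * (1 - subject_fat)) / (generic_mass * (1 - generic_fat))
    radial = float(np.sqrt(ffm_ratio / longitudinal))
    strength = ffm_ratio / longitudinal
    return ScaleFactors(longitudinal, radial, strength)


# ---------------------------------------------------------------------------
# RBF morph (triharmonic kernel + affine polynomial term)
# ---------------------------------------------------------------------------


def _triharmonic(r: np.ndarray) -> np.ndarray:
    return r**3


def rbf_morph(
    mesh: TriMesh,
    source: LandmarkSet,
    target: LandmarkSet,
    smoothing: float = 0.0,
) -> TriMesh:
    """Warp ``mesh`` so that source landmarks land on their targets.

    Interpolates the landmark displacement field with a triharmonic (r^3)
    kernel plus a first-order polynomial, so any globally affine landmark
    motion is reproduced exactly on every vertex.
    """
    src = source.positions
    tgt = target.aligned_to(source)
    n = len(src)
    if n < 4:
        raise ConditioningError("need at least 4 landmark pairs")
    # Non-coplanarity: rank of centred positions must be 3.
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-8) < 3:
        raise ConditioningError("landmarks are coplanar or degenerate")
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    if np.any(d2[~np.eye(n, dtype=bool)] < 1e-16):
        raise ConditioningError("duplicate landmark positions")
    K = _triharmonic(np.sqrt(d2)) + smoothing * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt - src
    try:
        coef = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("singular RBF interpolation system") from exc
    w, poly = coef[:n], coef[n:]

    def displace(points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points[:, None, :] - src[None, :, :], axis=-1)
        return _triharmonic(r) @ w + np.hstack(
            [np.ones((len(points), 1)), points]
        ) @ poly

    out = mesh.copy()
    out.vertices = mesh.vertices + displace(mesh.vertices)
    return out


def morph_points(
    points: np.ndarray, source: LandmarkSet, target: LandmarkSet
) -> np.ndarray:
    """Apply the same RBF warp to bare points (attachment sites etc.)."""
    carrier = TriMesh(
        np.vstack([points, points + [[0.0, 0.0, 1e-3]], points + [[0.0, 1e-3, 0.0]]]),
        np.arange(3 * len(points)).reshape(3, -1).T,
    )
    return rbf_morph(carrier, source, target).vertices[: len(points)]


# ---------------------------------------------------------------------------
# Closest-point projection onto a triangle surface
# ---------------------------------------------------------------------------


def closest_points_on_surface(
    points: np.ndarray, target: TriMesh, n_candidates: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on ``target`` for each query point.

    Candidate faces are pre-filtered with a KD-tree on face centroids;
    ``n_candidates`` is ample for the smooth, fairly uniform meshes used
    here.  Returns (foot points, distances).
    """
    if target.n_faces == 0:
        raise GeometryError("projection target mesh is empty")
    points = np.asarray(points, float).reshape(-1, 3)
    tree = cKDTree(target.face_centroids())
    k = min(n_candidates, target.n_faces)
    _, cand = tree.query(points, k=k)
    cand = cand.reshape(len(points), -1)
    tri = target.vertices[target.faces]  # (F,3,3)
    feet = np.empty_like(points)
    dists = np.empty(len(points))
    for i, p in enumerate(points):
        cp = _closest_on_triangles(p, tri[cand[i]])
        d2 = np.sum((cp - p) ** 2, axis=1)
        j = int(np.argmin(d2))
        feet[i] = cp[j]
        dists[i] = np.sqrt(d2[j])
    return feet, dists


def project_to_surface(mesh: TriMesh, target: TriMesh) -> TriMesh:
    """Move every vertex of ``mesh`` to its closest point on ``target``."""
    feet, _ = closest_points_on_surface(mesh.vertices, target)
    out = mesh.copy()
    out.vertices = feet
    return out


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle of ``tri`` (T,3,3).

    Ericson's region-based algorithm, vectorized over triangles.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    interior = a + v[:, None] * ab + w[:, None] * ac
    assign(np.ones(len(tri), dtype=bool), interior)
    return out
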