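"""Labeled triangle surface meshes and STL I/O.

Units are millimetres throughout.  Meshes carry a body/tissue ``label`` and a
per-face ``compartment`` tag (``"medial"``, ``"lateral"`` or ``"none"``) used
to split tibiofemoral contact totals.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kneesim.errors import StlFormatError

#: Vertex welding tolerance (mm); below scanner precision.
WELD_TOL = 1e-6

_COMPARTMENTS = ("medial", "lateral", "none")


@dataclass
class TriMesh:
    """Triangle surface mesh with optional compartment tags.

    Degenerate (zero-area) faces are dropped at construction; face indices
    are validated against the vertex count.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""
    compartment: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise IndexError(
                f"face indices out of range for {len(self.vertices)} vertices"
            )
        if self.compartment is None:
            comp = np.full(len(self.faces), "none", dtype="<U7")
        else:
            comp = np.asarray(self.compartment, dtype="<U7").reshape(-1)
            if len(comp) != len(self.faces):
                raise ValueError("compartment tags must be per-face")
            bad = set(np.unique(comp)) - set(_COMPARTMENTS)
            if bad:
                raise ValueError(f"unknown compartment tags: {sorted(bad)}")
        keep = _face_areas(self.vertices, self.faces) > 1e-12
        self.faces = self.faces[keep]
        self.compartment = comp[keep]

    # -- basic queries ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        return _face_areas(self.vertices, self.faces)

    def face_normals(self) -> np.ndarray:
        """Unit normals following the stored winding order."""
        n = _face_cross(self.vertices, self.faces)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        cross = _face_cross(self.vertices, self.faces)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], cross)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return vn / norms

    def tributary_areas(self) -> np.ndarray:
        """Per-vertex tributary area: one third of incident face areas (mm^2)."""
        areas = self.face_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], areas / 3.0)
        return out

    def vertex_compartments(self) -> np.ndarray:
        """Per-vertex tag by majority vote of incident face tags."""
        votes = {c: np.zeros(self.n_vertices) for c in _COMPARTMENTS}
        for c in _COMPARTMENTS:
            sel = self.compartment == c
            for k in range(3):
                np.add.at(votes[c], self.faces[sel, k], 1.0)
        stacked = np.stack([votes[c] for c in _COMPARTMENTS])
        return np.asarray(_COMPARTMENTS, dtype="<U7")[np.argmax(stacked, axis=0)]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (closed meshes)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- transforms ------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Rigidly/linearly mapped copy: v -> rotation @ v + translation."""
        verts = self.vertices @ np.asarray(rotation, float).T + np.asarray(
            translation, float
        )
        return TriMesh(verts, self.faces.copy(), self.label, self.compartment.copy())

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(), self.faces.copy(), self.label, self.compartment.copy()
        )

    def welded(self, tol: float = WELD_TOL) -> "TriMesh":
        """Copy with vertices closer than ``tol`` merged."""
        verts, faces = weld_vertices(self.vertices, self.faces, tol)
        return TriMesh(verts, faces, self.label, self.compartment.copy())


def _face_cross(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = vertices[faces]
    return np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if len(faces) == 0:
        return np.zeros(0)
    return 0.5 * np.linalg.norm(_face_cross(vertices, faces), axis=1)


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices on a ``tol``-spaced grid; returns (vertices, faces)."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][faces]


def combine(meshes: list[TriMesh], label: str = "") -> TriMesh:
    """Concatenate meshes into one surface, preserving compartment tags."""
    verts, faces, comps, off = [], [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        comps.append(m.compartment)
        off += m.n_vertices
    return TriMesh(
        np.concatenate(verts), np.concatenate(faces), label, np.concatenate(comps)
    )


# ---------------------------------------------------------------------------
# STL I/O (both binary and ASCII flavours; hand-rolled, no external deps)
# ---------------------------------------------------------------------------


def read_stl(path: str | Path, weld_tol: float = WELD_TOL) -> TriMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriMesh`.

    Raises :class:`StlFormatError` naming the byte offset on truncation.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) == 0:
        raise StlFormatError(f"{path}: empty file (0 bytes) at byte offset 0")
    if _looks_ascii(raw):
        tris = _parse_ascii(raw, path)
    else:
        tris = _parse_binary(raw, path)
    verts = tris.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    verts, faces = weld_vertices(verts, faces, weld_tol)
    return TriMesh(verts, faces, label=path.stem)


def write_stl(mesh: TriMesh, path: str | Path, ascii_format: bool = False) -> None:
    """Write ``mesh`` as binary (default) or ASCII STL."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if ascii_format:
        lines = [f"solid {mesh.label or 'kneesim'}"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.label or 'kneesim'}")
        path.write_text("\n".join(lines) + "\n")
        return
    with open(path, "wb") as fh:
        header = (mesh.label or "kneesim binary stl").encode()[:80]
        fh.write(header.ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(tri)))
        rec = np.zeros(len(tri), dtype=_BINARY_RECORD)
        rec["normal"] = normals
        rec["v"] = tri
        fh.write(rec.tobytes())


_BINARY_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
)


def _looks_ascii(raw: bytes) -> bool:
    if not raw.lstrip()[:5].lower() == b"solid":
        return False
    # A binary file may legally start with "solid": trust the binary size
    # header when it is self-consistent.
    if len(raw) >= 84:
        (n,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * n:
            return False
    return True


def _parse_binary(raw: bytes, path: Path) -> np.ndarray:
    if len(raw) < 84:
        raise StlFormatError(
            f"{path}: binary STL truncated in header at byte offset {len(raw)} (need 84)"
        )
    (n,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n
    if len(raw) < expected:
        raise StlFormatError(
            f"{path}: binary STL truncated at byte offset {len(raw)} "
            f"(header declares {n} facets, need {expected} bytes)"
        )
    rec = np.frombuffer(raw, dtype=_BINARY_RECORD, count=n, offset=84)
    return rec["v"].astype(np.float64)

def _parse_ascii(raw: bytes, path: Path) -> np.ndarray:
    try:
        text = raw.decode("utf-8", errors="strict")
    except UnicodeDecodeError as exc:
        raise StlFormatError(
            f"{path}: undecodable ASCII STL at byte offset {exc.start}"
        ) from exc
    coords: list[float] = []
    offset = 0
    in_loop = False
    for line in text.splitlines(keepends=True):
        stripped = line.strip().lower()
        if stripped.startswith("outer loop"):
            in_loop = True
        elif stripped.startswith("endloop"):
            in_loop = False
        elif stripped.startswith("vertex"):
            if not in_loop:
                raise StlFormatError(
                    f"{path}: vertex outside loop at byte offset {offset}"
                )
            parts = stripped.split()
            if len(parts) != 4:
                raise StlFormatError(
                    f"{path}: malformed vertex line at byte offset {offset}"
                )
            try:
                coords.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise StlFormatError(
                    f"{path}: unparseable coordinate at byte offset {offset}"
                ) from exc
        offset += len(line.encode("utf-8"))
    if len(coords) == 0 or len(coords) % 9 != 0:
        raise StlFormatError(
            f"{path}: ASCII STL ended with incomplete facet at byte offset {offset}"
        )
    return np.asarray(coords).reshape(-1, 3, 3)
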