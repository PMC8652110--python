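"""Triangular surface meshes: the geometric substrate of every descriptor.

Molecular surfaces (solvent-excluded surfaces and their synthetic analogs)
are closed, oriented triangle meshes with coordinates in Angstrom.  This
module reads and writes the two interchange formats used by surface
benchmarks (PLY, both ASCII and binary little-endian, and ASCII OFF),
validates the mesh contract, and derives the basic geometry every
descriptor needs: surface area, enclosed volume, area-weighted centroid
and angle-weighted outward vertex normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "MeshFormatError",
    "MeshTopologyError",
    "GeometrySummary",
    "read_mesh",
    "write_mesh",
    "mesh_geometry",
]


class MeshFormatError(ValueError):
    """File content violates the PLY/OFF triangle-mesh contract."""


class MeshTopologyError(ValueError):
    """Mesh is open, non-manifold or otherwise unusable for surface geometry."""


@dataclass
class TriangleMesh:
    """A triangle mesh: ``vertices`` (n, 3) float Angstrom, ``faces`` (m, 3) int.

    Optional unit ``normals`` (n, 3) are per-vertex.  Construction validates
    the index and degeneracy invariants; normals are checked for unit length.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array of vertex triples")
        if len(self.vertices) == 0:
            raise MeshFormatError("mesh has no vertices")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshFormatError("face indices out of range [0, n_vertices)")
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            idx = int(np.flatnonzero(degenerate)[0])
            raise MeshFormatError(f"degenerate triangle at face index {idx}")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.vertices.shape:
                raise MeshFormatError("normals must match vertices in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.abs(norms - 1.0).max() > 1e-6:
                raise MeshFormatError("vertex normals must be unit length (tol 1e-6)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy())

    def rotated(self, rotation: np.ndarray) -> "TriangleMesh":
        """Apply a 3x3 rotation matrix to the vertex coordinates."""
        R = np.asarray(rotation, dtype=float)
        return TriangleMesh(self.vertices @ R.T, self.faces.copy())

    def scaled(self, factor: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * float(factor), self.faces.copy())


@dataclass(frozen=True)
class GeometrySummary:
    """Surface area (A^2), enclosed volume (A^3), centroid and vertex normals."""

    area: float
    volume: float
    centroid: np.ndarray
    vertex_normals: np.ndarray
    flipped: bool  # True when orientation repair reversed all faces


def _format_from_path(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("ply", "off"):
            raise ValueError(f"unsupported mesh format {fmt!r}; use 'ply' or 'off'")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("ply", "off"):
        return suffix
    raise ValueError(f"cannot infer mesh format from path {path!r}")


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY (ASCII or binary LE) or OFF file into a :class:`TriangleMesh`.

    Vertex order is preserved; non-geometry properties (colour, confidence)
    are ignored.  Non-triangular faces raise :class:`MeshFormatError` naming
    the offending face.
    """
    fmt = _format_from_path(path, fmt)
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, validate=False)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise MeshFormatError(f"cannot parse {fmt.upper()} file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        raise MeshFormatError(f"{path} holds a scene, not a single mesh")
    faces = np.asarray(loaded.faces)
    # trimesh triangulates quads silently; detect the original arity for OFF/PLY
    raw_ok, bad = _check_triangular(path, fmt)
    if not raw_ok:
        raise MeshFormatError(f"non-triangular face at face index {bad} in {path}")
    mesh = TriangleMesh(np.asarray(loaded.vertices, dtype=np.float64), faces)
    n_comp = _n_components(mesh)
    if n_comp > 1:
        logger.warning("mesh %s has %d connected components", path, n_comp)
    return mesh


def _check_triangular(path: Path, fmt: str) -> tuple[bool, int | None]:
    """Scan face arity in the raw file; trimesh hides quad triangulation."""
    if fmt == "off":
        tokens: list[str] = []
        with open(path, "r", errors="replace") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    tokens.extend(line.split())
        if not tokens or tokens[0].upper() != "OFF":
            # headerless OFF variants: counts come first
            pass
        else:
            tokens = tokens[1:]
        if len(tokens) < 3:
            return True, None
        nv, nf = int(tokens[0]), int(tokens[1])
        pos = 3 + 3 * nv
        for i in range(nf):
            if pos >= len(tokens):
                break
            arity = int(tokens[pos])
            if arity != 3:
                return False, i
            pos += 1 + arity
        return True, None
    # PLY: ASCII headers declare the face element; binary needs no rescan
    # because trimesh errors out on mixed-arity binary lists.
    with open(path, "rb") as fh:
        header = fh.read(2048).decode("ascii", errors="replace")
    if "format ascii" not in header:
        return True, None
    lines = Path(path).read_text(errors="replace").splitlines()
    try:
        end = next(i for i, l in enumerate(lines) if l.strip() == "end_header")
    except StopIteration:
        return True, None
    counts = {}
    current = None
    for l in lines[:end]:
        parts = l.split()
        if parts and parts[0] == "element":
            current = parts[1]
            counts[current] = int(parts[2])
    nv = counts.get("vertex", 0)
    nf = counts.get("face", 0)
    face_lines = lines[end + 1 + nv : end + 1 + nv + nf]
    for i, l in enumerate(face_lines):
        parts = l.split()
        if parts and int(parts[0]) != 3:
            return False, i
    return True, None


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as ASCII PLY or OFF; round-trips exactly on topology and
    to 1e-6 on coordinates (9 significant digits, beyond binary float32)."""
    fmt = _format_from_path(path, fmt)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if fmt == "off":
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        else:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {mesh.n_vertices}\n"
                     "property double x\nproperty double y\nproperty double z\n"
                     f"element face {mesh.n_faces}\n"
                     "property list uchar int vertex_indices\n"
                     "end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _edge_map(faces: np.ndarray) -> dict:
    edges: dict[tuple[int, int], int] = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    return edges


def _n_components(mesh: TriangleMesh) -> int:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def is_closed(mesh: TriangleMesh) -> tuple[bool, int]:
    """Return (closed, boundary_edge_count): closed means every edge is shared
    by exactly two faces."""
    edges = _edge_map(mesh.faces)
    boundary = sum(1 for c in edges.values() if c != 2)
    return boundary == 0, boundary


def ensure_outward(mesh: TriangleMesh) -> tuple[TriangleMesh, bool]:
    """Flip all faces once if the divergence-theorem volume is negative."""
    if _signed_volume(mesh.vertices, mesh.faces) < 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy()), True
    return mesh, False


def mesh_geometry(mesh: TriangleMesh) -> GeometrySummary:
    """Area, enclosed volume, area-weighted centroid and angle-weighted
    outward unit vertex normals of a closed, consistently oriented mesh.

    Orientation is repaired (one global flip) when the signed volume is
    negative.  Open or non-manifold meshes raise :class:`MeshTopologyError`
    with the boundary edge count.
    """
    closed, boundary = is_closed(mesh)
    if not closed:
        raise MeshTopologyError(
            f"mesh is not closed/manifold: {boundary} boundary or non-manifold edges"
        )
    mesh, flipped = ensure_outward(mesh)
    V, F = mesh.vertices, mesh.faces
    v0, v1, v2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    face_area = 0.5 * np.linalg.norm(cross, axis=1)
    area = float(face_area.sum())
    volume = _signed_volume(V, F)
    tri_centroid = (v0 + v1 + v2) / 3.0
    centroid = (tri_centroid * face_area[:, None]).sum(axis=0) / area

    # angle-weighted vertex normals: each face normal contributes with the
    # interior angle at that vertex, which is robust on rough surfaces
    cross_norm = np.linalg.norm(cross, axis=1, keepdims=True)
    fn = np.divide(cross, np.maximum(cross_norm, 1e-300))  # zero-area faces -> 0
    normals = np.zeros_like(V)
    corners = (v0, v1, v2)
    for i in range(3):
        p = corners[i]
        q = corners[(i + 1) % 3]
        r = corners[(i + 2) % 3]
        e1 = q - p
        e2 = r - p
        den = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(den, 1e-300)
        ang = np.arccos(np.clip(np.nan_to_num(cosang, nan=1.0), -1.0, 1.0))
        np.add.at(normals, F[:, i], fn * ang[:, None])
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    normals = normals / lens
    return GeometrySummary(area=area, volume=volume, centroid=centroid,
                           vertex_normals=normals, flipped=flipped)
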