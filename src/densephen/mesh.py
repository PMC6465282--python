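"""Triangle-mesh and landmark containers with file I/O.

Meshes are plain vertex/face arrays in millimetres.  OBJ is the canonical
interchange format (1-based indices converted at the I/O boundary); PLY is
supported read-only.  Raw surface scans are messy — non-manifold edges are
tolerated, only strictly degenerate faces (repeated vertex indices) are
dropped — and the artifact detectors here (boundary vertices, oversized
triangles) feed the registration's correspondence-outlier model.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "LandmarkSet",
    "read_mesh",
    "write_mesh",
    "compute_vertex_normals",
    "detect_boundary_vertices",
    "flag_large_triangles",
    "read_landmarks",
    "write_landmarks",
    "closest_on_surface",
]


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) int.

    ``vertex_normals`` are computed lazily (area-weighted, unit length);
    ``isolated`` flags vertices with no incident face of nonzero area, whose
    normal is left at zero rather than NaN.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _normals: np.ndarray | None = field(default=None, repr=False)
    _isolated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValueError("faces must be (m, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            # degenerate faces (repeated indices) carry no geometry: drop
            f = self.faces
            ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
            if not ok.all():
                log.warning("dropping %d degenerate faces", int((~ok).sum()))
                self.faces = f[ok]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertex_normals(self) -> np.ndarray:
        if self._normals is None:
            compute_vertex_normals(self)
        return self._normals

    @property
    def isolated_vertices(self) -> np.ndarray:
        """Boolean mask of vertices with a degenerate normal umbrella."""
        if self._isolated is None:
            compute_vertex_normals(self)
        return self._isolated

    @property
    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def edge_lengths(self) -> np.ndarray:
        """Lengths of the unique undirected edges."""
        e = unique_edges(self.faces)
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new positions (normal cache invalidated)."""
        return TriangleMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy())


@dataclass
class LandmarkSet:
    """Named sparse landmarks: ordered ``names`` and (p, 3) ``coords`` in mm."""

    names: list[str]
    coords: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(len(self.names), 3)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.isfinite(self.coords).all():
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[self.names.index(name)]


# ---------------------------------------------------------------------------
# file I/O


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read an OBJ or PLY surface, fan-triangulating any polygonal faces.

    Vertex order is preserved as stored in the file.  Non-manifold input is
    accepted (scans are messy); a warning is logged.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    loaded = trimesh.load(path, file_type=fmt, process=False, maintain_order=True)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise IOError(f"no geometry in {path}")
        loaded = geoms[0]
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    mesh = TriangleMesh(verts, faces)
    if mesh.n_faces and len(detect_boundary_vertices(mesh)) and not _edges_manifold(mesh):
        log.warning("%s: non-manifold edges present (tolerated)", path.name)
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as Wavefront OBJ (v/f records, 1-based indices)."""
    path = Path(path)
    buf = io.StringIO()
    for v in mesh.vertices:
        buf.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
    for f in mesh.faces:
        buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    path.write_text(buf.getvalue())


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV into a LandmarkSet (mm, order preserved)."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"empty landmark file: {path}")
    if df[["x", "y", "z"]].isna().any().any():
        raise ValueError(f"missing coordinate in {path}")
    return LandmarkSet(
        names=[str(n) for n in df["name"]],
        coords=df[["x", "y", "z"]].to_numpy(dtype=np.float64),
    )


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {"name": lms.names, "x": lms.coords[:, 0], "y": lms.coords[:, 1], "z": lms.coords[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# derived geometry


def compute_vertex_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Area-weighted per-vertex normals, cached on the mesh.

    The cross product of two triangle edges has magnitude 2×area, so summing
    raw cross products per vertex is exactly the area weighting.  Vertices
    whose summed normal is (numerically) zero — isolated vertices or
    degenerate umbrellas — get a zero normal and are flagged, never NaN.
    """
    n = np.zeros_like(mesh.vertices)
    if mesh.n_faces:
        tri = mesh.triangles()
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        for c in range(3):
            np.add.at(n, mesh.faces[:, c], fn)
    norms = np.linalg.norm(n, axis=1)
    scale = mesh.bbox_diagonal or 1.0
    degenerate = norms <= 1e-12 * scale**2
    safe = np.where(degenerate, 1.0, norms)
    n = n / safe[:, None]
    n[degenerate] = 0.0
    mesh._normals = n
    mesh._isolated = degenerate
    return mesh


def unique_edges(faces: np.ndarray, return_counts: bool = False):
    """Unique undirected edges of a face array, optionally with use counts."""
    if not len(faces):
        e = np.empty((0, 2), dtype=np.int64)
        return (e, np.empty(0, dtype=np.int64)) if return_counts else e
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return (uniq, counts) if return_counts else uniq


def _edges_manifold(mesh: TriangleMesh) -> bool:
    _, counts = unique_edges(mesh.faces, return_counts=True)
    return bool((counts <= 2).all())


def detect_boundary_vertices(mesh: TriangleMesh) -> set[int]:
    """Vertices incident to an edge used by exactly one face (hole rims, rims)."""
    edges, counts = unique_edges(mesh.faces, return_counts=True)
    rim = edges[counts == 1]
    return set(np.unique(rim).tolist())


def flag_large_triangles(mesh: TriangleMesh, factor: float) -> set[int]:
    """Vertices of faces whose longest edge exceeds ``factor`` × median edge.

    Large triangles in a scan bridge badly captured or missing regions;
    correspondences into them are treated as outliers.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if mesh.n_faces < 1:
        raise ValueError("mesh has no faces")
    tri = mesh.triangles()
    side = np.stack(
        [
            np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
        ],
        axis=1,
    )
    median = np.median(mesh.edge_lengths())
    bad = side.max(axis=1) > factor * median
    return set(np.unique(mesh.faces[bad]).tolist())


# ---------------------------------------------------------------------------
# exact closest point on surface (used by shape-fit RMS and landmark transfer)


def closest_on_surface(
    mesh: TriangleMesh, points: np.ndarray, n_candidate_vertices: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest point on the triangulated surface for each query point.

    Candidate triangles are those incident to the ``n_candidate_vertices``
    nearest mesh vertices of each query (a nearest triangle always touches
    one of them for well-shaped meshes); the exact point-to-triangle
    projection is then evaluated on the candidates only.

    Returns ``(closest_points, distances, face_indices)``.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    # isolated vertices (e.g. inside holes) carry no surface: search only
    # vertices referenced by a face
    used = np.unique(mesh.faces)
    kv = min(n_candidate_vertices, len(used))
    tree = cKDTree(mesh.vertices[used])
    _, near = tree.query(points, k=kv)
    near = used[np.atleast_2d(near.reshape(len(points), kv))]

    # vertex -> incident faces as CSR
    order = np.argsort(mesh.faces.ravel(), kind="stable")
    face_of = order // 3
    vert_sorted = mesh.faces.ravel()[order]
    starts = np.searchsorted(vert_sorted, np.arange(mesh.n_vertices))
    ends = np.searchsorted(vert_sorted, np.arange(mesh.n_vertices), side="right")

    tri = mesh.triangles()
    out_pts = np.empty_like(points)
    out_d = np.empty(len(points))
    out_f = np.empty(len(points), dtype=np.int64)
    for i, vs in enumerate(near):
        cand = np.unique(
            np.concatenate([face_of[starts[v] : ends[v]] for v in vs])
        )
        q = np.broadcast_to(points[i], (len(cand), 3))
        cp = trimesh.triangles.closest_point(tri[cand], q)
        d2 = np.einsum("ij,ij->i", cp - q, cp - q)
        j = int(np.argmin(d2))
        out_pts[i] = cp[j]
        out_d[i] = np.sqrt(d2[j])
        out_f[i] = cand[j]
    return out_pts, out_d, out_f
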