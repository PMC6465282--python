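"""Landmark transfer via barycentric surface embeddings.

Because every registered surface shares the template's topology, a point
expressed as (triangle id, barycentric weights) on one mesh can be
reconstructed on any other mesh of the family — this coordinate conversion
moves sparse landmarks between target, registered-template and template
spaces.  Leave-one-out training averages the template-space positions of
all other faces' manual indications and converts the average onto the
held-out registered face, yielding automatic landmarks that are independent
of that face's own manual landmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh import LandmarkSet, TriangleMesh, closest_on_surface

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceEmbedding",
    "embed_point",
    "reconstruct_point",
    "pool_landmarks_on_template",
    "loo_automatic_landmarks",
    "screen_gross_errors",
]


@dataclass
class SurfaceEmbedding:
    """On-surface point as (face index, barycentric weights summing to 1)."""

    triangle_index: int
    barycentric: np.ndarray

    def __post_init__(self) -> None:
        self.barycentric = np.asarray(self.barycentric, dtype=np.float64).reshape(3)
        if (self.barycentric < -1e-9).any():
            raise ValueError("barycentric weights must be non-negative")
        if abs(self.barycentric.sum() - 1.0) > 1e-9:
            raise ValueError("barycentric weights must sum to 1")


def embed_point(mesh: TriangleMesh, point: np.ndarray) -> SurfaceEmbedding:
    """Embed a 3D point as its closest point on the surface.

    Any off-surface component (digitizing noise in a manual indication) is
    discarded by the projection.
    """
    cp, _, fidx = closest_on_surface(mesh, np.asarray(point, dtype=np.float64).reshape(1, 3))
    tri = mesh.vertices[mesh.faces[int(fidx[0])]][None]
    bary = trimesh.triangles.points_to_barycentric(tri, cp)[0]
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum()
    return SurfaceEmbedding(int(fidx[0]), bary)


def reconstruct_point(mesh: TriangleMesh, emb: SurfaceEmbedding) -> np.ndarray:
    """Evaluate an embedding on any mesh with the template's topology."""
    if not 0 <= emb.triangle_index < mesh.n_faces:
        raise IndexError(f"triangle index {emb.triangle_index} out of range")
    corners = mesh.vertices[mesh.faces[emb.triangle_index]]
    return emb.barycentric @ corners


def pool_landmarks_on_template(
    registered_meshes: list[TriangleMesh],
    template: TriangleMesh,
    manual_sets: list[list[LandmarkSet]],
) -> dict[str, np.ndarray]:
    """Pool manual indications from all faces into template space.

    ``manual_sets[i]`` holds the indications (one or more LandmarkSets) for
    face i, in the same physical space as ``registered_meshes[i]``.  Each
    indication is embedded on its registered mesh and reconstructed on the
    template.  Returns, per landmark name, the stacked template-space
    points (one row per indication per face).
    """
    if len(registered_meshes) != len(manual_sets):
        raise ValueError("one manual-indication list per registered mesh required")
    pooled: dict[str, list[np.ndarray]] = {}
    for reg, sets in zip(registered_meshes, manual_sets):
        if reg.n_faces != template.n_faces or reg.n_vertices != template.n_vertices:
            raise ValueError("registered mesh does not share template topology")
        for lset in sets:
            for name, p in zip(lset.names, lset.coords):
                emb = embed_point(reg, p)
                pooled.setdefault(name, []).append(reconstruct_point(template, emb))
    return {k: np.asarray(v) for k, v in pooled.items()}


def _transfer_template_points(
    template: TriangleMesh, registered: TriangleMesh, points: dict[str, np.ndarray]
) -> LandmarkSet:
    names, coords = [], []
    for name, p in points.items():
        emb = embed_point(template, p)  # re-project mean onto template surface
        names.append(name)
        coords.append(reconstruct_point(registered, emb))
    return LandmarkSet(names, np.asarray(coords), provenance="auto")


def loo_automatic_landmarks(
    registered_meshes: list[TriangleMesh],
    template: TriangleMesh,
    manual_sets: list[list[LandmarkSet]],
) -> list[LandmarkSet]:
    """Leave-one-out automatic landmarking.

    For each face, the template-space indications of *all other* faces are
    averaged per landmark, the mean is re-projected onto the template
    surface, and the embedding is reconstructed on the left-out registered
    face.  The result lies exactly on that face's surface and is
    independent of its own manual landmarks.
    """
    n = len(registered_meshes)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 faces")
    per_face: list[dict[str, np.ndarray]] = []
    for reg, sets in zip(registered_meshes, manual_sets):
        pts = pool_landmarks_on_template([reg], template, [sets])
        per_face.append({k: v.mean(axis=0) for k, v in pts.items()})
    names = list(per_face[0].keys())
    out = []
    for i in range(n):
        train = {
            name: np.mean([per_face[j][name] for j in range(n) if j != i], axis=0)
            for name in names
        }
        lset = _transfer_template_points(template, registered_meshes[i], train)
        lset.provenance = f"auto:loo:{i}"
        out.append(lset)
    return out


def screen_gross_errors(
    indications: list[LandmarkSet], threshold_sd: float = 6.0
) -> dict[str, list[int]]:
    """Flag indications far from the per-landmark mean of one face's repeats.

    Returns, per landmark, the indices of indications whose distance to the
    per-landmark mean exceeds ``threshold_sd`` × the RMS scatter of the
    repeats (gross coordinate errors such as a mistyped axis).
    """
    names = indications[0].names
    flagged: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        pts = np.asarray([ls.coords[ls.names.index(name)] for ls in indications])
        mean = pts.mean(axis=0)
        dists = np.linalg.norm(pts - mean, axis=1)
        sd = np.sqrt(np.mean(dists**2))
        if sd > 0:
            bad = np.nonzero(dists > threshold_sd * sd)[0]
            if bad.size:
                flagged[name] = bad.tolist()
    return flagged
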