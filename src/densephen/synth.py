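"""Synthetic fixtures: parametric surfaces, known warps, scan artifacts, and
multi-observer landmark studies with controlled variance components.

Every generator is a pure function of its seed.  The surfaces stand in for
facial scans: a bumpy sphere carries smooth anatomical-scale relief, the
face-like surface adds nose/brow/mouth bumps at canonical positions plus 19
named ground-truth landmark vertices mirroring a standard facial roster, so
validation code paths run unchanged on synthetic data.  Ground-truth warps
are sums of Gaussian radial basis functions — smooth deformations of the
same family the registration's Gaussian-convolution prior favors, so
recovery tests measure algorithmic error rather than model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .mesh import LandmarkSet, TriangleMesh
from .stats import ShapeSample

__all__ = [
    "SyntheticStudySpec",
    "make_surface",
    "rbf_warp",
    "degrade_scan",
    "simulate_landmark_study",
    "FACIAL_LANDMARK_NAMES",
]

# 7 midline + 12 bilateral — a standard facial anthropometric roster
FACIAL_LANDMARK_NAMES = [
    "glabella", "nasion", "pronasale", "subnasale",
    "labiale_superius", "labiale_inferius", "pogonion",
    "endocanthion_l", "endocanthion_r", "exocanthion_l", "exocanthion_r",
    "alar_curvature_l", "alar_curvature_r", "subalare_l", "subalare_r",
    "crista_philtri_l", "crista_philtri_r", "chelion_l", "chelion_r",
]


@dataclass
class SyntheticStudySpec:
    """Design of a simulated multi-observer landmark study.

    Defaults mirror a two-observer, three-iteration validation design on 41
    individuals with 19 landmarks.  Sigmas are per-coordinate Gaussian SDs
    in mm: ``sigma_individual`` is true biological shape variation,
    ``sigma_observer`` a systematic per-observer placement bias, and
    ``sigma_iteration`` the within-observer repeat (digitizing) noise.
    """

    n_individuals: int = 41
    n_observers: int = 2
    n_iterations: int = 3
    p_landmarks: int = 19
    sigma_individual: float = 3.0
    sigma_observer: float = 0.5
    sigma_interaction: float = 0.2
    sigma_iteration: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_observers", "n_iterations", "p_landmarks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sigma_individual", "sigma_observer", "sigma_interaction", "sigma_iteration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _sphere_bumps(directions: np.ndarray, centers: np.ndarray, amplitudes: np.ndarray,
                  width: float) -> np.ndarray:
    """Sum of Gaussians of great-circle angle between direction and centers."""
    cosang = np.clip(directions @ centers.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    return (np.exp(-(ang**2) / (2.0 * width**2)) * amplitudes).sum(axis=1)


# canonical bump layout for the face-like surface: (unit direction θ/φ-ish,
# amplitude as a fraction of radius, angular width in radians)
_FACE_BUMPS = [
    ((0.0, 0.25, 0.97), 0.18, 0.25),   # nose
    ((0.0, 0.55, 0.84), 0.06, 0.35),   # brow ridge
    ((0.0, -0.25, 0.97), 0.05, 0.22),  # mouth/chin region
    ((0.28, 0.45, 0.85), 0.04, 0.18),  # brow left
    ((-0.28, 0.45, 0.85), 0.04, 0.18), # brow right
]

# landmark directions on the unit sphere for the face-like roster
_FACE_LANDMARK_DIRS = {
    "glabella": (0.0, 0.50, 0.87), "nasion": (0.0, 0.40, 0.92),
    "pronasale": (0.0, 0.25, 0.97), "subnasale": (0.0, 0.12, 0.99),
    "labiale_superius": (0.0, -0.05, 1.0), "labiale_inferius": (0.0, -0.20, 0.98),
    "pogonion": (0.0, -0.45, 0.89),
    "endocanthion_l": (0.15, 0.38, 0.91), "endocanthion_r": (-0.15, 0.38, 0.91),
    "exocanthion_l": (0.38, 0.38, 0.85), "exocanthion_r": (-0.38, 0.38, 0.85),
    "alar_curvature_l": (0.14, 0.16, 0.98), "alar_curvature_r": (-0.14, 0.16, 0.98),
    "subalare_l": (0.10, 0.10, 0.99), "subalare_r": (-0.10, 0.10, 0.99),
    "crista_philtri_l": (0.05, -0.02, 1.0), "crista_philtri_r": (-0.05, -0.02, 1.0),
    "chelion_l": (0.22, -0.06, 0.97), "chelion_r": (-0.22, -0.06, 0.97),
}


def make_surface(
    kind: str = "icosphere",
    subdivisions: int = 3,
    seed: int = 0,
    radius: float = 80.0,
    bump_amplitude: float = 0.08,
    n_bumps: int = 8,
    bump_width: float = 0.4,
) -> TriangleMesh | tuple[TriangleMesh, LandmarkSet, np.ndarray]:
    """Watertight synthetic surface at facial scale (default radius 80 mm).

    ``icosphere``: plain icosphere.  ``bumpy_sphere``: seeded smooth radial
    bumps (sum of Gaussians on the sphere; amplitude as a fraction of the
    radius).  ``face_like``: fixed nose/brow/mouth bumps plus 19 named
    landmark vertices — returns (mesh, landmarks, landmark_vertex_ids).
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(base.vertices, dtype=np.float64)
    dirs = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.asarray(base.faces, dtype=np.int64)

    if kind == "icosphere":
        return TriangleMesh(dirs * radius, faces)
    if kind == "bumpy_sphere":
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_bumps, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = rng.uniform(-1.0, 1.0, size=n_bumps) * bump_amplitude
        r = radius * (1.0 + _sphere_bumps(dirs, centers, amps, bump_width))
        return TriangleMesh(dirs * r[:, None], faces)
    if kind == "face_like":
        # widths differ per bump: evaluate each separately
        r = np.ones(len(dirs))
        for (c, a, w) in _FACE_BUMPS:
            cdir = np.asarray(c) / np.linalg.norm(c)
            r += a * np.exp(-np.arccos(np.clip(dirs @ cdir, -1, 1)) ** 2 / (2 * w**2))
        mesh = TriangleMesh(dirs * (radius * r)[:, None], faces)
        ids = []
        for name in FACIAL_LANDMARK_NAMES:
            d = np.asarray(_FACE_LANDMARK_DIRS[name], dtype=np.float64)
            d /= np.linalg.norm(d)
            ids.append(int(np.argmax(dirs @ d)))
        ids = np.asarray(ids)
        lms = LandmarkSet(FACIAL_LANDMARK_NAMES, mesh.vertices[ids], provenance="ground_truth")
        return mesh, lms, ids
    raise ValueError(f"unknown surface kind {kind!r}")


def rbf_warp(
    mesh: TriangleMesh,
    n_centers: int = 6,
    amplitude: float = 5.0,
    length_scale: float = 40.0,
    seed: int = 0,
) -> tuple[TriangleMesh, np.ndarray]:
    """Smooth Gaussian-RBF warp of a mesh with exact ground truth.

    Displacement at x is ``sum_c a_c exp(-|x-c|^2 / (2 l^2))`` with centers
    sampled on the surface and coefficient vectors scaled so the maximum
    vertex displacement equals ``amplitude`` (mm).  Returns the warped mesh
    (same topology) and the exact per-vertex ground-truth positions (which
    equal the warped mesh's vertices — the topology-sharing map).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    verts = mesh.vertices
    if amplitude == 0:
        return mesh.copy(), verts.copy()
    rng = np.random.default_rng(seed)
    centers = verts[rng.choice(len(verts), size=n_centers, replace=False)]
    coeff = rng.normal(size=(n_centers, 3))
    diff = verts[:, None, :] - centers[None, :, :]
    k = np.exp(-np.einsum("ijk,ijk->ij", diff, diff) / (2.0 * length_scale**2))
    disp = k @ coeff
    peak = np.linalg.norm(disp, axis=1).max()
    if peak > 0:
        disp *= amplitude / peak
    warped = verts + disp
    return TriangleMesh(warped, mesh.faces.copy()), warped.copy()


def degrade_scan(
    mesh: TriangleMesh,
    hole_fraction: float = 0.0,
    noise_sigma: float = 0.0,
    n_spikes: int = 0,
    seed: int = 0,
    spike_length: float | None = None,
) -> tuple[TriangleMesh, dict]:
    """Simulate scan artifacts: disk-shaped holes, vertex noise, spikes.

    Holes are grown as face patches around seeded faces until roughly
    ``hole_fraction`` of faces are removed; ``noise_sigma`` (mm) is i.i.d.
    Gaussian vertex jitter; ``n_spikes`` vertices are pushed far outward
    along their normal, creating oversized triangles.  Returns the degraded
    mesh and an info dict (``removed_faces``, ``hole_vertices``,
    ``spike_vertices``).
    """
    if not 0.0 <= hole_fraction < 0.5:
        raise ValueError("hole_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    verts = mesh.vertices.copy()
    faces = mesh.faces.copy()
    info: dict = {"removed_faces": np.empty(0, dtype=np.int64),
                  "hole_vertices": np.empty(0, dtype=np.int64),
                  "spike_vertices": np.empty(0, dtype=np.int64)}

    if hole_fraction > 0 and len(faces):
        target_n = int(round(hole_fraction * len(faces)))
        adjacency = _face_adjacency(faces)
        removed: set[int] = set()
        seeds = rng.choice(len(faces), size=min(3, len(faces)), replace=False)
        per_patch = max(target_n // len(seeds), 1)
        for s in seeds:
            frontier = [int(s)]
            patch: set[int] = set()
            while frontier and len(patch) < per_patch:
                f = frontier.pop(0)
                if f in patch or f in removed:
                    continue
                patch.add(f)
                frontier.extend(adjacency.get(f, ()))
            removed |= patch
        removed_ids = np.asarray(sorted(removed), dtype=np.int64)
        keep = np.ones(len(faces), dtype=bool)
        keep[removed_ids] = False
        info["removed_faces"] = removed_ids
        info["hole_vertices"] = np.unique(faces[removed_ids])
        faces = faces[keep]

    if noise_sigma > 0:
        verts = verts + rng.normal(scale=noise_sigma, size=verts.shape)

    if n_spikes > 0:
        normals = mesh.vertex_normals
        ids = rng.choice(len(verts), size=n_spikes, replace=False)
        length = spike_length if spike_length is not None else 0.25 * mesh.bbox_diagonal
        verts[ids] = verts[ids] + normals[ids] * length
        info["spike_vertices"] = np.asarray(ids, dtype=np.int64)

    return TriangleMesh(verts, faces), info


def _face_adjacency(faces: np.ndarray) -> dict[int, list[int]]:
    """Edge-sharing face adjacency."""
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_faces.setdefault(key, []).append(fi)
    adj: dict[int, list[int]] = {}
    for flist in edge_faces.values():
        for f in flist:
            adj.setdefault(f, []).extend(g for g in flist if g != f)
    return adj


def simulate_landmark_study(
    spec: SyntheticStudySpec, base_config: np.ndarray | None = None
) -> ShapeSample:
    """Simulate a crossed individual × observer × iteration landmark study.

    configuration(ind, obs, it) = base + individual(ind) + observer(obs)
    + interaction(ind, obs) + iteration noise — each effect i.i.d. Gaussian
    per landmark coordinate with its sigma.  Fully seeded and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p_landmarks
    if base_config is None:
        base = rng.uniform(-50.0, 50.0, size=(p, 3))
    else:
        base = np.asarray(base_config, dtype=np.float64)
        if base.shape != (p, 3):
            raise ValueError("base_config must be (p_landmarks, 3)")
    ind_eff = rng.normal(scale=spec.sigma_individual, size=(spec.n_individuals, p, 3))
    obs_eff = rng.normal(scale=spec.sigma_observer, size=(spec.n_observers, p, 3))
    ixo_eff = rng.normal(
        scale=spec.sigma_interaction, size=(spec.n_individuals, spec.n_observers, p, 3)
    )
    configs, rows = [], []
    for i in range(spec.n_individuals):
        for o in range(spec.n_observers):
            for t in range(spec.n_iterations):
                noise = rng.normal(scale=spec.sigma_iteration, size=(p, 3))
                configs.append(base + ind_eff[i] + obs_eff[o] + ixo_eff[i, o] + noise)
                rows.append({"individual": f"ind{i:03d}", "observer": f"obs{o}",
                             "iteration": f"it{t}"})
    names = (FACIAL_LANDMARK_NAMES if p == len(FACIAL_LANDMARK_NAMES)
             else [f"lm{j:02d}" for j in range(p)])
    return ShapeSample(np.asarray(configs), pd.DataFrame(rows), names)
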