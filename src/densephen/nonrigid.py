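"""Visco-elastic non-rigid registration.

After rigid alignment the template is deformed into the target by a
displacement field that is regularized two ways each iteration: the
per-iteration increment (velocity) is smoothed — the *viscous* part — and
the accumulated displacement is smoothed — the *elastic* part — by repeated
Gaussian convolution over the template's k-nearest-neighbor graph.  The
number of convolution passes anneals linearly from a high initial value
(noisy early correspondences, near-rigid motion) down to a low final value
(fine local adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .correspondence import build_correspondences
from .inliers import deterministic_flags, stochastic_weights, target_artifact_vertices
from .mesh import TriangleMesh, closest_on_surface

log = logging.getLogger(__name__)

__all__ = [
    "AnnealingSchedule",
    "NonRigidConfig",
    "DeformationField",
    "smoothing_passes_at",
    "gaussian_smooth_field",
    "nonrigid_register",
    "shape_fit_rms",
]


@dataclass
class AnnealingSchedule:
    """Linear annealing of smoothing passes over the iterations.

    ``viscous_*`` passes smooth the per-iteration velocity; ``elastic_*``
    passes smooth the total accumulated displacement.  Start values should
    be ≥ end values (high smoothing first, relaxed later).
    """

    num_iterations: int = 60
    viscous_start: int = 50
    viscous_end: int = 1
    elastic_start: int = 50
    elastic_end: int = 1
    smoothing_k: int = 10

    def __post_init__(self) -> None:
        if self.num_iterations < 1:
            raise ValueError("num_iterations must be >= 1")
        for a, b in ((self.viscous_start, self.viscous_end), (self.elastic_start, self.elastic_end)):
            if b < 0 or a < b:
                raise ValueError("schedule requires start >= end >= 0")


def smoothing_passes_at(schedule: AnnealingSchedule, t: int) -> tuple[int, int]:
    """(viscous, elastic) pass counts at iteration ``t`` (1-based), linearly
    interpolated from start to end and rounded to the nearest integer."""
    if not 1 <= t <= schedule.num_iterations:
        raise ValueError("iteration index out of schedule range")
    if schedule.num_iterations == 1:
        frac = 0.0
    else:
        frac = (t - 1) / (schedule.num_iterations - 1)

    def interp(a: int, b: int) -> int:
        return int(round(a + (b - a) * frac))

    return (
        interp(schedule.viscous_start, schedule.viscous_end),
        interp(schedule.elastic_start, schedule.elastic_end),
    )


def _smoothing_operator(
    positions: np.ndarray, weights: np.ndarray, k: int
) -> sp.csr_matrix:
    """Row-stochastic Gaussian k-NN smoothing operator over the vertex cloud.

    Kernel of vertex i over its k nearest neighbors (self included at
    distance 0) is a Gaussian with bandwidth equal to i's k-th-neighbor
    distance, multiplied by the neighbors' inlier weights (floored at a
    small epsilon so zero-weight regions inherit motion from their inlier
    neighbors rather than freezing).
    """
    n = len(positions)
    k = min(k, n)
    tree = cKDTree(positions)
    d, idx = tree.query(positions, k=k)
    d = d.reshape(n, k)
    idx = idx.reshape(n, k)
    scale = max(float(np.abs(positions).max()), 1.0)
    sigma = np.maximum(d[:, -1], 1e3 * np.finfo(np.float64).eps * scale)
    g = np.exp(-(d**2) / (2.0 * sigma[:, None] ** 2))
    w = np.maximum(np.asarray(weights, dtype=np.float64), 1e-6)
    g = g * w[idx]
    g /= g.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n), k)
    return sp.csr_matrix((g.ravel(), (rows, idx.ravel())), shape=(n, n))


def gaussian_smooth_field(
    field_vectors: np.ndarray,
    positions: np.ndarray,
    weights: np.ndarray | None,
    passes: int,
    k: int = 10,
) -> np.ndarray:
    """Apply ``passes`` Gaussian k-NN convolutions to a per-vertex 3-vector field.

    Each pass replaces every vector by the inlier-weighted Gaussian average
    over its neighborhood; a constant field is a fixed point (rows sum
    to 1).  ``passes=0`` returns the input unchanged.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    f = np.asarray(field_vectors, dtype=np.float64)
    if passes == 0:
        return f.copy()
    if weights is None:
        weights = np.ones(len(f))
    op = _smoothing_operator(np.asarray(positions, dtype=np.float64), weights, k)
    out = f.copy()
    for _ in range(passes):
        out = op @ out
    return out


@dataclass
class DeformationField:
    """Total per-vertex displacement and the last per-iteration increment."""

    displacements: np.ndarray
    velocity: np.ndarray


@dataclass
class NonRigidConfig:
    k: int = 3
    push_pull_balance: float = 0.5
    kappa: float = 3.0
    inlier_updates: int = 10
    coverage_rms: float | None = None  # mm; None = iteration-count stopping only
    large_triangle_factor: float = 3.0
    use_inlier_weights: bool = True


@dataclass
class NonRigidTrace:
    rms: list[float] = field(default_factory=list)
    mean_inlier_weight: list[float] = field(default_factory=list)


def nonrigid_register(
    rigid_template: TriangleMesh,
    target: TriangleMesh,
    schedule: AnnealingSchedule | None = None,
    config: NonRigidConfig | None = None,
) -> tuple[TriangleMesh, DeformationField, NonRigidTrace]:
    """Deform the rigidly aligned template onto the target surface.

    Per iteration: symmetric correspondences and inlier weights → raw
    velocity ``v_i = c_i − x_i`` → viscous smoothing of v → displacement
    update ``d ← d + v`` → elastic smoothing of d → ``x ← x0 + d``.  Stops
    at the scheduled iteration count, or earlier once the shape-fit RMS
    reaches ``config.coverage_rms`` if that is set.  Output topology is
    identical to the template's.
    """
    schedule = schedule or AnnealingSchedule()
    config = config or NonRigidConfig()
    x0 = rigid_template.vertices.copy()
    faces = rigid_template.faces
    x = x0.copy()
    d = np.zeros_like(x0)
    v = np.zeros_like(x0)
    artifacts = target_artifact_vertices(target, config.large_triangle_factor)
    trace = NonRigidTrace()

    current = rigid_template.copy()
    for t in range(1, schedule.num_iterations + 1):
        normals = current.vertex_normals
        corr, fwd = build_correspondences(
            x, target.vertices, target.vertex_normals, config.k, config.push_pull_balance
        )
        corr = deterministic_flags(corr, normals, fwd, artifacts)
        if config.use_inlier_weights:
            resid = np.linalg.norm(corr.positions - x, axis=1)
            corr.inlier_weights = stochastic_weights(
                resid, n_updates=config.inlier_updates, kappa=config.kappa, flags=corr.flags
            )
        vis, ela = smoothing_passes_at(schedule, t)
        v = corr.positions - x
        v = gaussian_smooth_field(v, x, corr.inlier_weights, vis, schedule.smoothing_k)
        d = d + v
        d = gaussian_smooth_field(d, x, corr.inlier_weights, ela, schedule.smoothing_k)
        if not np.isfinite(d).all():
            raise RuntimeError(f"non-finite deformation field at iteration {t}")
        x = x0 + d
        current = TriangleMesh(x, faces)
        _, dist, _ = closest_on_surface(target, x)
        rms = float(np.sqrt(np.mean(dist**2)))
        trace.rms.append(rms)
        trace.mean_inlier_weight.append(float(corr.inlier_weights.mean()))
        log.info("nonrigid iter %d: shape-fit RMS %.6g mm (visc %d, elast %d)", t, rms, vis, ela)
        if config.coverage_rms is not None and rms <= config.coverage_rms:
            log.info("coverage reached at iteration %d", t)
            break
    return current, DeformationField(displacements=d, velocity=v), trace


def shape_fit_rms(registered: TriangleMesh | np.ndarray, target: TriangleMesh) -> float:
    """RMS over template vertices of exact point-to-surface distance (mm).

    The distance is to the closest point on any target *triangle*, not to
    the nearest target vertex.
    """
    if target.n_faces == 0:
        raise ValueError("target mesh is empty")
    pts = registered.vertices if isinstance(registered, TriangleMesh) else np.asarray(registered)
    _, d, _ = closest_on_surface(target, pts)
    return float(np.sqrt(np.mean(d**2)))
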