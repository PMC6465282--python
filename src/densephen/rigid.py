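"""Scaled rigid (similarity) registration by weighted iterative closest point.

The transform model is restricted to translation, rotation and isotropic
scale.  Each iteration recomputes symmetric correspondences and inlier
weights, then solves the weighted similarity Procrustes problem in closed
form (SVD of the weighted cross-covariance with determinant sign
correction, so reflections are never returned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .correspondence import build_correspondences
from .inliers import deterministic_flags, stochastic_weights, target_artifact_vertices
from .mesh import TriangleMesh, closest_on_surface

log = logging.getLogger(__name__)

__all__ = ["SimilarityTransform", "estimate_similarity", "apply_similarity", "rigid_register"]


@dataclass
class SimilarityTransform:
    """x ↦ scale · rotation · x + translation (scale > 0, det(rotation) = +1)."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        rinv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=rinv,
            translation=-rinv @ self.translation / self.scale,
        )

    def matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        a = m[:3, :3]
        s = float(np.cbrt(np.linalg.det(a)))
        if s <= 0:
            raise ValueError("matrix is not a positive-scale similarity")
        return cls(s, a / s, m[:3, 3])

    def save(self, path) -> None:
        np.savetxt(path, self.matrix(), fmt="%.12g")

    @classmethod
    def load(cls, path) -> "SimilarityTransform":
        return cls.from_matrix(np.loadtxt(path))


def apply_similarity(transform: SimilarityTransform, points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    return pts @ (transform.scale * transform.rotation).T + transform.translation


def estimate_similarity(
    floating_points: np.ndarray,
    corresponding_points: np.ndarray,
    weights: np.ndarray | None = None,
    estimate_scale: bool = True,
) -> SimilarityTransform:
    """Weighted least-squares similarity transform (closed form).

    Minimizes ``sum_i w_i ||s R f_i + t - c_i||^2`` via weighted centroids,
    the SVD of the weighted cross-covariance with determinant sign
    correction (rejecting reflections), and the trace-corrected variance
    ratio for the isotropic scale.
    """
    f = np.asarray(floating_points, dtype=np.float64)
    c = np.asarray(corresponding_points, dtype=np.float64)
    w = np.ones(len(f)) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    wn = w / w.sum()
    fbar = wn @ f
    cbar = wn @ c
    fc = f - fbar
    cc = c - cbar
    cov = (cc * wn[:, None]).T @ fc  # 3x3, maps floating frame -> target frame
    u, s, vt = np.linalg.svd(cov)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate support: effective points are collinear or coincident")
    d = np.sign(np.linalg.det(u @ vt))
    dmat = np.diag([1.0, 1.0, d])
    rot = u @ dmat @ vt
    if estimate_scale:
        var_f = float(wn @ np.einsum("ij,ij->i", fc, fc))
        if var_f <= 0:
            raise ValueError("degenerate support: floating points coincident")
        scale = float(np.trace(np.diag(s) @ dmat)) / var_f
        if scale <= 0:
            raise ValueError("negative scale solution (fully reflected correspondence)")
    else:
        scale = 1.0
    trans = cbar - scale * rot @ fbar
    return SimilarityTransform(scale, rot, trans)


@dataclass
class RigidConfig:
    k: int = 3
    push_pull_balance: float = 0.5
    kappa: float = 3.0
    inlier_updates: int = 10
    max_iterations: int = 30
    tolerance_factor: float = 1e-5  # × target bbox diagonal
    estimate_scale: bool = True
    large_triangle_factor: float = 3.0
    use_inlier_weights: bool = True


@dataclass
class RegistrationTrace:
    rms: list[float] = field(default_factory=list)
    mean_inlier_weight: list[float] = field(default_factory=list)


def rigid_register(
    template: TriangleMesh,
    target: TriangleMesh,
    config: RigidConfig | None = None,
    init_landmarks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SimilarityTransform, TriangleMesh, RegistrationTrace]:
    """Register the template to the target with a scaled rigid ICP loop.

    ``init_landmarks``: optional (template_points, target_points) pairs for a
    rough initial alignment when the surfaces start in very different poses.
    Returns the total transform, the transformed template, and the
    per-iteration shape-fit RMS trace.
    """
    config = config or RigidConfig()
    total = SimilarityTransform.identity()
    if init_landmarks is not None:
        lf, lt = init_landmarks
        total = estimate_similarity(lf, lt, estimate_scale=config.estimate_scale)

    x = apply_similarity(total, template.vertices)
    normals0 = template.vertex_normals
    normals = normals0 @ total.rotation.T
    artifacts = target_artifact_vertices(target, config.large_triangle_factor)
    tol = config.tolerance_factor * target.bbox_diagonal

    trace = RegistrationTrace()
    _, d0, _ = closest_on_surface(target, x)
    rms_prev = float(np.sqrt(np.mean(d0**2)))
    trace.rms.append(rms_prev)
    trace.mean_inlier_weight.append(1.0)
    grew = 0
    for it in range(config.max_iterations):
        corr, fwd = build_correspondences(
            x, target.vertices, target.vertex_normals, config.k, config.push_pull_balance
        )
        corr = deterministic_flags(corr, normals, fwd, artifacts)
        if config.use_inlier_weights:
            resid = np.linalg.norm(corr.positions - x, axis=1)
            corr.inlier_weights = stochastic_weights(
                resid, n_updates=config.inlier_updates, kappa=config.kappa, flags=corr.flags
            )
        step = estimate_similarity(
            x, corr.positions, corr.inlier_weights, estimate_scale=config.estimate_scale
        )
        total = step.compose(total)
        x = apply_similarity(step, x)
        normals = normals0 @ total.rotation.T

        _, d, _ = closest_on_surface(target, x)
        rms = float(np.sqrt(np.mean(d**2)))
        trace.rms.append(rms)
        trace.mean_inlier_weight.append(float(corr.inlier_weights.mean()))
        log.info("rigid iter %d: shape-fit RMS %.6g mm", it + 1, rms)
        if rms > rms_prev:
            grew += 1
            if grew >= 5:
                raise RuntimeError(
                    f"rigid registration diverging: RMS grew 5 consecutive iterations "
                    f"(last {rms:.6g} mm at iteration {it + 1})"
                )
        else:
            grew = 0
        if abs(rms_prev - rms) < tol:
            rms_prev = rms
            break
        rms_prev = rms
    return total, template.with_vertices(x), trace
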