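"""Correspondence-outlier handling.

Scan artifacts (hole rims, oversized triangles bridging missing data) and
statistical outliers are down-weighted so they do not drive the transform
update.  Deterministic flags and stochastic re-weighting compose
multiplicatively; flagged/zero-weight vertices still *move* with the
estimated transform — they contribute nothing to its estimation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .correspondence import CorrespondenceSet
from .mesh import TriangleMesh, detect_boundary_vertices, flag_large_triangles

__all__ = ["deterministic_flags", "stochastic_weights", "target_artifact_vertices"]


def target_artifact_vertices(target: TriangleMesh, large_triangle_factor: float = 3.0) -> np.ndarray:
    """Mask of target vertices on hole rims, oversized triangles, or no face."""
    bad = np.zeros(target.n_vertices, dtype=bool)
    if target.n_faces:
        bad[:] = True
        bad[np.unique(target.faces)] = False  # faceless vertices are artifacts
    idx = detect_boundary_vertices(target)
    if idx:
        bad[list(idx)] = True
    if target.n_faces:
        idx = flag_large_triangles(target, large_triangle_factor)
        if idx:
            bad[list(idx)] = True
    return bad


def deterministic_flags(
    corr: CorrespondenceSet,
    floating_normals: np.ndarray,
    forward_affinity: sp.csr_matrix,
    target_artifacts: np.ndarray,
) -> CorrespondenceSet:
    """Flag correspondences into artifacts or onto back-facing surface.

    A floating vertex is flagged when (a) its dominant target neighbor (the
    largest forward-affinity column) lies on an artifact, or (b) its own
    normal opposes the fused correspondence normal (a front surface matched
    to the back of the scan).  Flagged vertices get inlier weight 0.
    """
    fa = forward_affinity.tocsr()
    dominant = np.empty(fa.shape[0], dtype=np.int64)
    for i in range(fa.shape[0]):
        lo, hi = fa.indptr[i], fa.indptr[i + 1]
        dominant[i] = fa.indices[lo + np.argmax(fa.data[lo:hi])]
    flags = np.asarray(target_artifacts, dtype=bool)[dominant]
    facing = np.einsum("ij,ij->i", np.asarray(floating_normals), corr.normals)
    flags = flags | (facing < 0.0)
    corr.flags = flags
    corr.inlier_weights = np.where(flags, 0.0, corr.inlier_weights)
    return corr


def stochastic_weights(
    distances: np.ndarray,
    prior_weights: np.ndarray | None = None,
    n_updates: int = 10,
    kappa: float = 3.0,
    flags: np.ndarray | None = None,
) -> np.ndarray:
    """Iteratively re-weighted Gaussian inlier weights from residual distances.

    Each update estimates the weighted residual variance
    ``sigma^2 = sum(w d^2) / sum(w)`` and sets
    ``w = exp(-d^2 / (2 kappa^2 sigma^2))`` — residuals beyond ``kappa``
    residual-RMS units decay rapidly.  A perfect fit (all zero distances)
    keeps every weight at 1.  Deterministic flags, if given, zero the final
    weights multiplicatively.
    """
    if n_updates < 1:
        raise ValueError("n_updates must be >= 1")
    d = np.asarray(distances, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    w = np.ones_like(d) if prior_weights is None else np.asarray(prior_weights, dtype=np.float64).copy()
    d2 = d**2
    eps = np.finfo(np.float64).tiny
    for _ in range(n_updates):
        denom = w.sum()
        if denom <= 0:
            w = np.ones_like(d)
            denom = w.sum()
        sigma2 = max(float((w * d2).sum() / denom), eps)
        if sigma2 <= eps:  # all residuals zero: perfect fit
            w = np.ones_like(d)
            break
        w = np.exp(-d2 / (2.0 * kappa**2 * sigma2))
    if flags is not None:
        w = w * (1.0 - np.asarray(flags, dtype=np.float64))
    return np.clip(w, 0.0, 1.0)
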