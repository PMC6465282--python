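"""Geometric-morphometric validation statistics.

Landmark error metrics, centroid size, Generalized Procrustes Analysis,
Procrustes ANOVA (sequential/Type-I sums of squares on aligned coordinates
in the Goodall trace form, with residual-randomization permutation p),
agreement statistics (ICC, Bland–Altman), observer-error summaries
(Levene's test, paired t), dense average shapes, and PCA compactness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .mesh import TriangleMesh

__all__ = [
    "ShapeSample",
    "AnovaTable",
    "euclidean_error",
    "rmse_per_axis",
    "centroid_size",
    "gpa_align",
    "procrustes_anova",
    "anova_univariate",
    "icc_agreement",
    "bland_altman",
    "observer_error_sd",
    "levene_test",
    "paired_t",
    "average_shape",
    "pca_compactness",
]


@dataclass
class ShapeSample:
    """Stacked landmark configurations (n × p × 3, mm) with per-row factors.

    ``labels`` carries one row per configuration (columns such as
    individual, observer, iteration, method) for the ANOVA models.
    """

    configurations: np.ndarray
    labels: pd.DataFrame = None
    landmark_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, dtype=np.float64)
        if self.configurations.ndim != 3 or self.configurations.shape[2] != 3:
            raise ValueError("configurations must be (n, p, 3)")
        if self.labels is None:
            self.labels = pd.DataFrame(index=range(len(self.configurations)))
        if len(self.labels) != len(self.configurations):
            raise ValueError("labels must have one row per configuration")

    @property
    def n(self) -> int:
        return self.configurations.shape[0]

    @property
    def p(self) -> int:
        return self.configurations.shape[1]

    def flat(self) -> np.ndarray:
        """(n, 3p) coordinate matrix."""
        return self.configurations.reshape(self.n, -1)


@dataclass
class AnovaTable:
    """Sequential-SS ANOVA table plus residual and total rows."""

    table: pd.DataFrame  # columns: factor, Df, SS, MS, R2, F, p_perm
    residual: dict = field(default_factory=dict)
    total_ss: float = 0.0

    def __str__(self) -> str:
        rows = self.table.copy()
        rows.loc[len(rows)] = [
            "Residuals", self.residual["Df"], self.residual["SS"],
            self.residual["MS"], self.residual["SS"] / self.total_ss if self.total_ss else 0.0,
            np.nan, np.nan,
        ]
        rows.loc[len(rows)] = ["Total", sum(rows["Df"]), self.total_ss, np.nan, 1.0, np.nan, np.nan]
        return rows.to_string(index=False, float_format=lambda v: f"{v:.4f}")


# ---------------------------------------------------------------------------
# error metrics


def _merge_batches(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    for df in (a, b):
        missing = {"face_id", "landmark", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"landmark batch missing columns {sorted(missing)}")
    m = a.merge(b, on=["face_id", "landmark"], suffixes=("_a", "_b"), validate="one_to_one")
    if len(m) != len(a) or len(m) != len(b):
        raise ValueError("face/landmark sets do not match between batches")
    return m


def euclidean_error(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-landmark mean Euclidean distance over faces, and the grand mean (mm).

    Inputs are batch tables (face_id, landmark, x, y, z), one row per face
    and landmark, matched across the two batches.
    """
    m = _merge_batches(a, b)
    d = np.sqrt(
        (m["x_a"] - m["x_b"]) ** 2 + (m["y_a"] - m["y_b"]) ** 2 + (m["z_a"] - m["z_b"]) ** 2
    )
    per_landmark = d.groupby(m["landmark"]).mean()
    return per_landmark, float(per_landmark.mean())


def rmse_per_axis(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-landmark RMSE along x, y, z separately (mm), over matched faces."""
    m = _merge_batches(a, b)
    out = {}
    for ax in "xyz":
        sq = (m[f"{ax}_a"] - m[f"{ax}_b"]) ** 2
        out[f"rmse_{ax}"] = np.sqrt(sq.groupby(m["landmark"]).mean())
    return pd.DataFrame(out)


def centroid_size(config: np.ndarray) -> float:
    """√Σ‖x_k − x̄‖²: the standard geometric-morphometric size measure."""
    config = np.asarray(config, dtype=np.float64)
    if config.ndim != 2 or len(config) < 2:
        raise ValueError("configuration must be (p>=2, dim)")
    c = config - config.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis


def _proper_rotation(source: np.ndarray, dest: np.ndarray) -> np.ndarray:
    """Rotation (det +1) minimizing ‖source·R − dest‖_F for centered configs."""
    u, s, vt = np.linalg.svd(source.T @ dest)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0] * (len(s) - 1) + [d]) @ vt


def gpa_align(sample: ShapeSample, scale: bool = True, tol: float = 1e-10,
              max_iter: int = 200) -> tuple[ShapeSample, np.ndarray]:
    """Generalized Procrustes Analysis.

    Centers every configuration, optionally scales each to unit centroid
    size, then iteratively rotates all configurations to the evolving mean
    shape until the mean stabilizes.  Returns the aligned sample and the
    mean shape.  Deterministic given input order.
    """
    if sample.n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    X = sample.configurations.copy()
    X -= X.mean(axis=1, keepdims=True)
    cs = np.sqrt((X**2).sum(axis=(1, 2)))
    if (cs <= 0).any():
        raise ValueError("degenerate (all-coincident) configuration")
    if scale:
        X /= cs[:, None, None]
    mean = X[0].copy()
    mean /= np.sqrt((mean**2).sum()) if scale else 1.0
    for _ in range(max_iter):
        for i in range(len(X)):
            X[i] = X[i] @ _proper_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        if scale:
            nrm = np.sqrt((new_mean**2).sum())
            if nrm > 0:
                new_mean /= nrm
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = ShapeSample(X, sample.labels.copy(), sample.landmark_names)
    return aligned, mean


# ---------------------------------------------------------------------------
# sequential-SS linear models (Procrustes ANOVA / univariate ANOVA)


def _term_columns(labels: pd.DataFrame, term: str) -> np.ndarray:
    """Full dummy coding of a factor term ('a' or crossed 'a:b')."""
    factors = term.split(":")
    for f in factors:
        if f not in labels.columns:
            raise ValueError(f"unknown factor {f!r} in model term {term!r}")
    combo = labels[factors[0]].astype(str)
    for f in factors[1:]:
        combo = combo + "\x1f" + labels[f].astype(str)
    return pd.get_dummies(combo, dtype=np.float64).to_numpy()


def _sequential_bases(labels: pd.DataFrame, terms: list[str]) -> tuple[list[np.ndarray], np.ndarray]:
    """Orthonormal bases for each term's incremental column space.

    The intercept is projected out first; each term's dummy columns are then
    orthogonalized against everything before it.  A term adding no new
    dimensions is aliased with earlier terms → error.
    """
    n = len(labels)
    q_prev = np.full((n, 1), 1.0 / np.sqrt(n))  # intercept
    bases = []
    for term in terms:
        d = _term_columns(labels, term)
        d = d - q_prev @ (q_prev.T @ d)
        u, s, _ = np.linalg.svd(d, full_matrices=False)
        # dummy columns have norm ~sqrt(n); anything below this absolute scale
        # is numerical residue of an aliased column, not a new dimension
        keep = s > 1e-8 * np.sqrt(n)
        if not keep.any():
            raise ValueError(f"model term {term!r} is aliased with earlier terms")
        q = u[:, keep]
        bases.append(q)
        q_prev = np.hstack([q_prev, q])
    return bases, q_prev


def _sequential_anova(
    Y: np.ndarray,
    labels: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnovaTable:
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    bases, _ = _sequential_bases(labels, terms)
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    ss_terms, dfs = [], []
    for q in bases:
        proj = q.T @ Y
        ss_terms.append(float((proj**2).sum()))
        dfs.append(q.shape[1])
    df_res = n - 1 - sum(dfs)
    if df_res < 0:
        raise ValueError("model is over-parameterized (negative residual df)")
    ss_res = max(ss_total - sum(ss_terms), 0.0)
    if ss_res <= 1e-12 * max(ss_total, 1e-300):  # saturated model: exact fit
        ss_res = 0.0
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    ms = [s / d for s, d in zip(ss_terms, dfs)]
    with np.errstate(divide="ignore", invalid="ignore"):
        fvals = [
            (m / ms_res) if (ms_res and np.isfinite(ms_res) and ms_res > 0) else
            (0.0 if m == 0 else np.inf)
            for m in ms
        ]

    # residual-randomization permutation p per term (reduced-model residuals)
    pvals = [np.nan] * len(terms)
    if n_permutations > 0 and df_res > 0 and ms_res > 0:
        rng = np.random.default_rng(seed)
        q_red = np.full((n, 1), 1.0 / np.sqrt(n))
        all_q = np.hstack([q_red] + bases)
        for k, qk in enumerate(bases):
            fitted = q_red @ (q_red.T @ Y)
            resid = Y - fitted
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                Ystar = fitted + resid[perm]
                ss_k = float(((qk.T @ Ystar) ** 2).sum())
                tot = float(((Ystar - Ystar.mean(axis=0)) ** 2).sum())
                explained = float(((all_q[:, 1:].T @ Ystar) ** 2).sum())
                ss_r = max(tot - explained, 0.0)
                if ss_r <= 0:
                    fstar = np.inf if ss_k > 0 else 0.0
                else:
                    fstar = (ss_k / dfs[k]) / (ss_r / df_res)
                if fstar >= fvals[k] - 1e-12:
                    count += 1
            pvals[k] = (count + 1) / (n_permutations + 1)
            q_red = np.hstack([q_red, qk])

    table = pd.DataFrame(
        {
            "factor": terms,
            "Df": dfs,
            "SS": ss_terms,
            "MS": ms,
            "R2": [s / ss_total if ss_total > 0 else 0.0 for s in ss_terms],
            "F": fvals,
            "p_perm": pvals,
        }
    )
    return AnovaTable(
        table=table,
        residual={"Df": df_res, "SS": ss_res, "MS": ms_res},
        total_ss=ss_total,
    )


def procrustes_anova(
    aligned: ShapeSample,
    terms: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnovaTable:
    """Procrustes ANOVA on aligned shape coordinates (Goodall trace form).

    Each configuration is flattened to a 3p-vector; sums of squares are
    accumulated across all coordinates and partitioned sequentially
    (Type I) over the model terms in the order given.  Nested designs are
    expressed as interaction terms (e.g. iteration within observer as
    ``observer:iteration`` after the ``observer`` main effect).  Permutation
    p-values use residual randomization of the reduced model per term.
    """
    return _sequential_anova(aligned.flat(), aligned.labels, terms, n_permutations, seed)


def anova_univariate(
    response: np.ndarray,
    labels: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnovaTable:
    """Sequential-SS ANOVA with a scalar response (e.g. centroid size)."""
    return _sequential_anova(np.asarray(response, dtype=np.float64), labels, terms,
                             n_permutations, seed)


# ---------------------------------------------------------------------------
# agreement statistics


def icc_agreement(measurements: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n subjects × k raters) table.  The
    absolute-agreement form penalizes systematic offsets between raters,
    unlike a correlation.
    """
    x = np.asarray(measurements, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n>=2, k>=2) table")
    if not np.isfinite(x).all():
        raise ValueError("table must be complete")
    n, k = x.shape
    grand = x.mean()
    rm = x.mean(axis=1)
    cm = x.mean(axis=0)
    ssr = k * ((rm - grand) ** 2).sum()
    ssc = n * ((cm - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    if sst == 0:
        return 1.0  # identical raters on identical subjects
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate zero-variance table")
    return float((msr - mse) / denom)


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean paired difference and 95% limits of agreement (mean ± 1.96 SD)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 matched pairs")
    d = x - y
    m = float(d.mean())
    s = float(d.std(ddof=1))
    return m, (m - 1.96 * s, m + 1.96 * s)


def observer_error_sd(batch: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-landmark, per-axis SD of repeated indications, averaged over faces.

    ``batch`` holds one row per repeat: face_id, landmark, x, y, z (repeats
    = iterations of one observer for intra-observer error, or per-observer
    averages for inter-observer error).  Returns the per-landmark table of
    mean SDs along each axis and the grand mean over landmarks and axes.
    """
    need = {"face_id", "landmark", "x", "y", "z"}
    if not need.issubset(batch.columns):
        raise ValueError(f"batch missing columns {sorted(need - set(batch.columns))}")
    counts = batch.groupby(["face_id", "landmark"]).size()
    if (counts < 2).any():
        raise ValueError("every face/landmark cell needs >= 2 repeats")
    per_cell = batch.groupby(["face_id", "landmark"])[["x", "y", "z"]].std(ddof=1)
    per_landmark = per_cell.groupby("landmark").mean()
    per_landmark.columns = ["sd_x", "sd_y", "sd_z"]
    return per_landmark, float(per_landmark.to_numpy().mean())


def levene_test(groups: list[np.ndarray], center: str = "median") -> tuple[float, float]:
    """Levene's test for equality of variances across groups.

    One-way ANOVA on absolute deviations from each group's center (median
    by default — the robust Brown–Forsythe variant, appropriate when the
    values themselves are non-normal, e.g. distributions of SDs).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    cfun = np.median if center == "median" else np.mean
    z = [np.abs(np.asarray(g, dtype=np.float64) - cfun(g)) for g in groups]
    n = sum(len(g) for g in z)
    kg = len(z)
    grand = np.concatenate(z).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    f = (ss_between / (kg - 1)) / (ss_within / (n - kg))
    p = float(scipy.stats.f.sf(f, kg - 1, n - kg))
    return float(f), p


def paired_t(x: np.ndarray, y: np.ndarray, two_sided: bool = True) -> tuple[float, float]:
    """Paired t-test on matched samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 matched pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return (np.inf if d.mean() > 0 else -np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = float(scipy.stats.t.sf(abs(t), n - 1))
    if two_sided:
        p *= 2.0
    return float(t), p


# ---------------------------------------------------------------------------
# dense-shape summaries


def average_shape(meshes: list[TriangleMesh], pre_align: bool = False) -> TriangleMesh:
    """Vertex-wise average of registered surfaces sharing template topology.

    With ``pre_align`` the vertex sets are first GPA-aligned (no scaling),
    removing residual pose differences before averaging.
    """
    if not meshes:
        raise ValueError("no meshes to average")
    f0 = meshes[0].faces
    for m in meshes[1:]:
        if m.n_vertices != meshes[0].n_vertices or not np.array_equal(m.faces, f0):
            raise ValueError("meshes do not share template topology")
    stack = np.stack([m.vertices for m in meshes])
    if pre_align and len(meshes) > 1:
        sample, _ = gpa_align(ShapeSample(stack, pd.DataFrame(index=range(len(stack)))), scale=False)
        stack = sample.configurations
    return TriangleMesh(stack.mean(axis=0), f0.copy())


def pca_compactness(
    data: ShapeSample | np.ndarray, thresholds: tuple[float, ...] = (0.95, 0.98)
) -> tuple[np.ndarray, dict[float, int]]:
    """Eigenvalue spectrum of the shape sample and components-to-threshold.

    Fewer components needed for a variance threshold indicates more
    consistent point indication across the sample (minimum-description-
    length reading of registration quality).
    """
    X = data.flat() if isinstance(data, ShapeSample) else np.asarray(data, dtype=np.float64)
    if X.ndim != 2 or len(X) < 3:
        raise ValueError("need >= 3 samples")
    Xc = X - X.mean(axis=0)
    _, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (len(X) - 1)
    total = eig.sum()
    counts = {}
    if total <= 0:
        return eig, {t: 0 for t in thresholds}
    cum = np.cumsum(eig) / total
    for t in thresholds:
        counts[t] = int(np.searchsorted(cum, t - 1e-12) + 1)
    return eig, counts
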