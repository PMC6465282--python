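"""Morphometric statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.transform import Rotation

from densephen import (
    ShapeSample,
    TriangleMesh,
    anova_univariate,
    average_shape,
    bland_altman,
    centroid_size,
    euclidean_error,
    gpa_align,
    icc_agreement,
    levene_test,
    observer_error_sd,
    paired_t,
    pca_compactness,
    procrustes_anova,
    rmse_per_axis,
)


def batch(face_ids, names, coords):
    rows = []
    for f, cfg in zip(face_ids, coords):
        for n, c in zip(names, cfg):
            rows.append({"face_id": f, "landmark": n, "x": c[0], "y": c[1], "z": c[2]})
    return pd.DataFrame(rows)


class TestErrorMetrics:
    def test_identical_zero(self, rng):
        a = batch(["f1", "f2"], ["p", "q"], rng.normal(size=(2, 2, 3)))
        per, grand = euclidean_error(a, a)
        assert (per == 0).all() and grand == 0

    def test_three_four_five(self, rng):
        coords = rng.normal(size=(3, 2, 3))
        a = batch(["f1", "f2", "f3"], ["p", "q"], coords)
        b = batch(["f1", "f2", "f3"], ["p", "q"], coords + [3.0, 4.0, 0.0])
        per, grand = euclidean_error(a, b)
        np.testing.assert_allclose(per.to_numpy(), 5.0, atol=1e-12)
        assert grand == pytest.approx(5.0)

    def test_rmse_constant_offset(self, rng):
        coords = rng.normal(size=(4, 3, 3))
        a = batch(list("abcd"), ["p", "q", "r"], coords)
        b = batch(list("abcd"), ["p", "q", "r"], coords + [0.5, 0.0, 0.0])
        r = rmse_per_axis(a, b)
        np.testing.assert_allclose(r["rmse_x"], 0.5, atol=1e-12)
        np.testing.assert_allclose(r[["rmse_y", "rmse_z"]], 0.0, atol=1e-12)

    def test_rmse_matches_formula(self, rng):
        ca, cb = rng.normal(size=(5, 2, 3)), rng.normal(size=(5, 2, 3))
        a = batch(list("abcde"), ["p", "q"], ca)
        b = batch(list("abcde"), ["p", "q"], cb)
        r = rmse_per_axis(a, b)
        expected = np.sqrt(((ca - cb) ** 2).mean(axis=0))  # (2 landmarks, 3 axes)
        np.testing.assert_allclose(r.loc[["p", "q"]].to_numpy(), expected, atol=1e-12)

    def test_mismatched_names_error(self, rng):
        a = batch(["f1"], ["p"], rng.normal(size=(1, 1, 3)))
        b = batch(["f1"], ["z"], rng.normal(size=(1, 1, 3)))
        with pytest.raises(ValueError):
            euclidean_error(a, b)


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert centroid_size(sq) == pytest.approx(np.sqrt(2.0))

    def test_homogeneity_and_invariance(self, rng):
        cfg = rng.normal(size=(19, 3))
        cs = centroid_size(cfg)
        assert centroid_size(cfg * 2.7) == pytest.approx(2.7 * cs)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        assert centroid_size(cfg @ R.T + 5.0) == pytest.approx(cs, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((1, 3)))


class TestGPA:
    def test_transformed_copies_collapse(self, rng):
        base = rng.normal(size=(10, 3))
        configs = []
        for _ in range(6):
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            s = rng.uniform(0.5, 2.0)
            t = rng.normal(size=3) * 10
            configs.append(s * base @ R.T + t)
        aligned, mean = gpa_align(ShapeSample(np.asarray(configs)), scale=True)
        for c in aligned.configurations:
            np.testing.assert_allclose(c, aligned.configurations[0], atol=1e-9)

    def test_contract_centered_unit_cs(self, rng):
        sample = ShapeSample(rng.normal(size=(5, 8, 3)))
        aligned, _ = gpa_align(sample, scale=True)
        for c in aligned.configurations:
            np.testing.assert_allclose(c.mean(axis=0), 0.0, atol=1e-9)
            assert centroid_size(c) == pytest.approx(1.0, abs=1e-9)

    def test_two_configs_match_pairwise_procrustes(self, rng):
        """n=2 GPA equals the direct orthogonal-Procrustes pair solution."""
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        aligned, _ = gpa_align(ShapeSample(np.stack([a, b])), scale=True)
        d_gpa = np.linalg.norm(aligned.configurations[0] - aligned.configurations[1])

        ac = (a - a.mean(0)) / centroid_size(a)
        bc = (b - b.mean(0)) / centroid_size(b)
        u, s, vt = np.linalg.svd(bc.T @ ac)
        d = np.sign(np.linalg.det(u @ vt))
        R = u @ np.diag([1, 1, d]) @ vt
        d_pair = np.linalg.norm(ac - bc @ R)
        assert d_gpa == pytest.approx(d_pair, abs=1e-8)

    def test_rotation_invariance(self, rng):
        sample = rng.normal(size=(6, 10, 3))
        a1, m1 = gpa_align(ShapeSample(sample.copy()), scale=True)
        rotated = np.einsum(
            "nij,kj->nik", sample, Rotation.from_euler("z", 77, degrees=True).as_matrix()
        )
        a2, m2 = gpa_align(ShapeSample(rotated), scale=True)
        # Procrustes distances between configurations are preserved
        d1 = np.linalg.norm(a1.configurations - a1.configurations.mean(0))
        d2 = np.linalg.norm(a2.configurations - a2.configurations.mean(0))
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            gpa_align(ShapeSample(np.zeros((3, 4, 3))))


def toy_labels(rng, n, levels=("g1", "g2")):
    return pd.DataFrame({"group": rng.choice(levels, size=n)})


class TestSequentialAnova:
    def test_constant_response_zero_ss(self, rng):
        labels = pd.DataFrame({"g": ["a", "b"] * 5})
        tab = anova_univariate(np.ones(10), labels, ["g"], n_permutations=0)
        assert tab.table.SS[0] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_two_group_hand_computed(self):
        """Means 0 and 1, four samples each, zero noise: SS_between = 2."""
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        labels = pd.DataFrame({"g": list("aaaabbbb")})
        tab = anova_univariate(y, labels, ["g"], n_permutations=0)
        assert tab.table.SS[0] == pytest.approx(2.0)
        assert tab.residual["SS"] == pytest.approx(0.0, abs=1e-12)
        assert tab.table.F[0] == np.inf

    def test_matches_statsmodels_type1(self, rng):
        """Sequential SS equals statsmodels anova_lm typ=1 on a crossed design."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        n = 48
        df = pd.DataFrame(
            {
                "a": rng.choice(["x", "y", "z"], size=n),
                "b": rng.choice(["u", "v"], size=n),
            }
        )
        df["y"] = rng.normal(size=n) + (df.a == "x") * 1.5 + (df.b == "u") * 0.7
        tab = anova_univariate(df["y"].to_numpy(), df[["a", "b"]], ["a", "b", "a:b"],
                               n_permutations=0)
        fit = smf.ols("y ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        np.testing.assert_allclose(tab.table.SS.to_numpy(), ref["sum_sq"].iloc[:3], atol=1e-9)
        np.testing.assert_allclose(tab.residual["SS"], ref["sum_sq"].iloc[3], atol=1e-9)
        np.testing.assert_allclose(tab.table.F.to_numpy(), ref["F"].iloc[:3], atol=1e-9)

    def test_ss_decomposition_sums_to_total(self, rng):
        n = 36
        labels = pd.DataFrame(
            {"a": rng.choice(list("pq"), n), "b": rng.choice(list("rst"), n)}
        )
        Y = rng.normal(size=(n, 12))
        tab = procrustes_anova(ShapeSample(Y.reshape(n, 4, 3), labels), ["a", "b"],
                               n_permutations=0)
        assert tab.table.SS.sum() + tab.residual["SS"] == pytest.approx(tab.total_ss, rel=1e-9)

    def test_single_coordinate_reduces_to_classic_f(self, rng):
        """Goodall trace F with p=1 landmark, 1 informative axis equals the
        classic one-way ANOVA F."""
        n = 30
        g = rng.choice(["a", "b", "c"], size=n)
        y = rng.normal(size=n) + (g == "a") * 1.0
        cfg = np.zeros((n, 1, 3))
        cfg[:, 0, 0] = y
        tab = procrustes_anova(
            ShapeSample(cfg, pd.DataFrame({"g": g})), ["g"], n_permutations=0
        )
        f_ref = scipy.stats.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"]).statistic
        assert tab.table.F[0] == pytest.approx(f_ref, rel=1e-9)

    def test_rank_deficient_design_error(self):
        labels = pd.DataFrame({"a": list("xxyy"), "b": list("xxyy")})  # aliased
        with pytest.raises(ValueError, match="aliased"):
            anova_univariate(np.arange(4.0), labels, ["a", "b"], n_permutations=0)

    def test_permutation_p_small_for_strong_effect(self, rng):
        labels = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12})
        y = np.concatenate([rng.normal(size=12), rng.normal(size=12) + 8.0])
        tab = anova_univariate(y, labels, ["g"], n_permutations=199, seed=1)
        assert tab.table.p_perm[0] <= 0.01

    def test_permutation_seed_reproducible(self, rng):
        labels = pd.DataFrame({"g": rng.choice(["a", "b"], 20)})
        y = rng.normal(size=20)
        t1 = anova_univariate(y, labels, ["g"], n_permutations=99, seed=7)
        t2 = anova_univariate(y, labels, ["g"], n_permutations=99, seed=7)
        assert t1.table.p_perm[0] == t2.table.p_perm[0]


class TestICC:
    def test_identical_raters(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc_agreement(x) == pytest.approx(1.0)

    def test_bias_penalized_below_pearson(self, rng):
        a = rng.normal(size=30)
        x = np.column_stack([a, a + 5.0])
        icc = icc_agreement(x)
        r = np.corrcoef(x.T)[0, 1]
        assert icc < r

    def test_matches_pingouin(self, rng):
        """ICC(A,1) equals pingouin's ICC2 (two-way random, absolute agreement)."""
        import pingouin as pg

        x = rng.normal(size=(12, 3)) + np.arange(12)[:, None]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_agreement(x) == pytest.approx(icc2, abs=1e-9)


class TestBlandAltman:
    def test_identical(self, rng):
        x = rng.normal(size=10)
        m, (lo, hi) = bland_altman(x, x)
        assert m == lo == hi == 0

    def test_normal_differences_limits(self):
        rng = np.random.default_rng(0)
        sigma = 0.75
        x = rng.normal(size=20000)
        y = x + rng.normal(scale=sigma, size=20000)
        _, (lo, hi) = bland_altman(y, x)
        assert hi == pytest.approx(1.96 * sigma, rel=0.05)
        assert lo == pytest.approx(-1.96 * sigma, rel=0.05)

    def test_too_few(self):
        with pytest.raises(ValueError):
            bland_altman(np.zeros(2), np.zeros(2))


class TestObserverErrorSd:
    def test_identical_repeats_zero(self):
        rows = []
        for it in range(3):
            rows.append({"face_id": "f", "landmark": "p", "x": 1.0, "y": 2.0, "z": 3.0})
        tab, grand = observer_error_sd(pd.DataFrame(rows))
        assert grand == 0

    def test_two_repeat_sd(self):
        delta = 0.6
        rows = [
            {"face_id": "f", "landmark": "p", "x": -delta, "y": 0.0, "z": 0.0},
            {"face_id": "f", "landmark": "p", "x": delta, "y": 0.0, "z": 0.0},
        ]
        tab, _ = observer_error_sd(pd.DataFrame(rows))
        assert tab.loc["p", "sd_x"] == pytest.approx(np.sqrt(2) * delta)
        assert tab.loc["p", "sd_y"] == 0

    def test_single_repeat_error(self):
        df = pd.DataFrame([{"face_id": "f", "landmark": "p", "x": 0.0, "y": 0.0, "z": 0.0}])
        with pytest.raises(ValueError):
            observer_error_sd(df)


class TestLeveneAndT:
    def test_levene_identical_groups(self):
        g = np.array([1.0, 2, 3, 4])
        f, p = levene_test([g, g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("center", ["median", "mean"])
    def test_levene_matches_scipy(self, rng, center):
        g1 = rng.normal(size=15)
        g2 = rng.normal(scale=3.0, size=12)
        g3 = rng.normal(scale=0.5, size=20)
        f, p = levene_test([g1, g2, g3], center=center)
        ref = scipy.stats.levene(g1, g2, g3, center=center)
        assert f == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_paired_t_identical(self, rng):
        x = rng.normal(size=10)
        t, p = paired_t(x, x)
        assert t == 0 and p == 1

    def test_paired_t_matches_scipy(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(scale=0.5, size=25) + 0.2
        t, p = paired_t(x, y)
        ref = scipy.stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_paired_t_constant_difference_limit(self):
        x = np.arange(5.0)
        t, p = paired_t(x + 1.0, x)
        assert t == np.inf and p == 0


class TestAverageShape:
    def test_identical_meshes(self, bumpy):
        avg = average_shape([bumpy.copy(), bumpy.copy()])
        np.testing.assert_allclose(avg.vertices, bumpy.vertices, atol=1e-12)

    def test_mirror_average_on_plane(self, bumpy):
        mirrored = bumpy.with_vertices(bumpy.vertices * [1.0, 1.0, -1.0])
        avg = average_shape([bumpy, mirrored])
        np.testing.assert_allclose(avg.vertices[:, 2], 0.0, atol=1e-12)

    def test_nonrigid_average_sharper_than_rigid_closest_point(self, bumpy):
        """Averaging true (homologous) vertex positions preserves bump
        amplitude; averaging nearest-point (non-homologous) matches blurs it."""
        from densephen import rbf_warp
        from densephen.mesh import closest_on_surface

        family, truths = [], []
        for s in range(4):
            w, t = rbf_warp(bumpy, amplitude=6.0, seed=20 + s)
            family.append(w)
            truths.append(t)
        homologous = average_shape(family)

        # rigid-only stand-in: map template vertices to closest point on each target
        cp_stack = []
        for w in family:
            cp, _, _ = closest_on_surface(w, bumpy.vertices)
            cp_stack.append(cp)
        rigid_avg = np.mean(cp_stack, axis=0)

        true_avg = np.mean(truths, axis=0)
        err_hom = np.linalg.norm(homologous.vertices - true_avg, axis=1).mean()
        err_rigid = np.linalg.norm(rigid_avg - true_avg, axis=1).mean()
        assert err_hom < err_rigid

    def test_topology_mismatch_error(self, bumpy, icosphere):
        with pytest.raises(ValueError):
            average_shape([bumpy, icosphere])


class TestPcaCompactness:
    def test_identical_shapes_zero_variance(self):
        X = np.tile(np.arange(12.0), (5, 1))
        eig, counts = pca_compactness(X)
        assert counts[0.95] == 0 or eig.sum() < 1e-20

    def test_three_modes(self, rng):
        modes = np.linalg.qr(rng.normal(size=(30, 3)))[0].T  # 3 orthonormal modes
        scores = rng.normal(size=(40, 3)) * [5.0, 3.0, 1.0]
        X = scores @ modes
        eig, counts = pca_compactness(X)
        assert counts[0.98] == 3
        assert eig[:3].sum() / eig.sum() > 0.999

    def test_noise_increases_components(self, rng):
        modes = np.linalg.qr(rng.normal(size=(30, 3)))[0].T
        scores = rng.normal(size=(40, 3)) * [5.0, 3.0, 1.0]
        X = scores @ modes
        Xn = X + rng.normal(scale=0.5, size=X.shape)
        _, c_clean = pca_compactness(X)
        _, c_noisy = pca_compactness(Xn)
        assert c_noisy[0.98] > c_clean[0.98]
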