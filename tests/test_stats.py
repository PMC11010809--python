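import numpy as np
import pytest
from scipy.stats import f_oneway

from scalemorph.stats import (pairwise_permanova, pc_shape_vectors, pca_fit,
                              permanova, shape_size_regression,
                              significance_stars, size_group_tests)

from conftest import rotate


class TestPCA:
    def test_diagonal_cloud_pc1(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=300)
        data = np.column_stack((t, t)) + rng.normal(size=(300, 2), scale=1e-3)
        model = pca_fit(data)
        np.testing.assert_allclose(np.abs(model.eigenvectors[0]),
                                   [1 / np.sqrt(2)] * 2, atol=1e-3)
        assert model.variance_fractions[0] > 0.999

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 7))
        model = pca_fit(data)
        np.testing.assert_allclose(model.inverse_transform(model.scores), data,
                                   atol=1e-9)

    def test_scores_covariance_is_eigenvalues(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        model = pca_fit(data)
        cov = np.cov(model.scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues), atol=1e-9)

    def test_orthonormal_rows_and_sign_convention(self):
        rng = np.random.default_rng(3)
        model = pca_fit(rng.normal(size=(30, 5)))
        np.testing.assert_allclose(model.eigenvectors @ model.eigenvectors.T,
                                   np.eye(5), atol=1e-9)
        for row in model.eigenvectors:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.ones((5, 3)))


class TestPCShapeVectors:
    def test_excursions_symmetric_about_mean(self):
        rng = np.random.default_rng(4)
        model = pca_fit(rng.normal(size=(30, 8)))
        lo, hi = pc_shape_vectors(model, 0, 2.0)
        np.testing.assert_allclose((lo + hi) / 2, model.mean.reshape(-1, 2),
                                   atol=1e-9)

    def test_small_magnitude_converges_to_mean(self):
        rng = np.random.default_rng(5)
        model = pca_fit(rng.normal(size=(30, 8)))
        lo, hi = pc_shape_vectors(model, 0, 1e-9)
        np.testing.assert_allclose(lo, model.mean.reshape(-1, 2), atol=1e-7)
        np.testing.assert_allclose(hi, lo, atol=1e-7)

    def test_eft_context_widens_ellipses(self):
        # dataset of 1-harmonic rows varying only in a1 (ellipse width)
        rng = np.random.default_rng(6)
        a1 = 2.0 + rng.normal(size=40, scale=0.3)
        rows = np.column_stack((a1, np.zeros(40), np.zeros(40), np.ones(40)))
        model = pca_fit(rows)
        lo, hi = pc_shape_vectors(model, 0, 2.0, context="eft_coefs")
        w_lo = np.ptp(lo.vertices[:, 0])
        w_hi = np.ptp(hi.vertices[:, 0])
        h_lo = np.ptp(lo.vertices[:, 1])
        assert abs(w_hi - w_lo) > 0.5          # widths differ strongly
        assert h_lo == pytest.approx(2.0, abs=1e-6)  # heights unchanged

    def test_magnitude_validation(self):
        model = pca_fit(np.random.default_rng(7).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            pc_shape_vectors(model, 0, 0.0)


class TestPermanova:
    def test_hand_enumerated_two_group_example(self):
        """A = {0, 1}, B = {2, 3}: F = 8, R2 = 0.8, exact p = 2/6."""
        res = permanova(np.array([0.0, 1, 2, 3]), ["A", "A", "B", "B"])
        assert res.exhaustive
        assert res.pseudo_F == pytest.approx(8.0, abs=1e-9)
        assert res.R2 == pytest.approx(0.8, abs=1e-9)
        assert res.p_raw == pytest.approx(1 / 3, abs=1e-12)

    def test_duplicated_multiset_null(self):
        rng = np.random.default_rng(8)
        block = rng.normal(size=(6, 3))
        data = np.vstack((block, block))
        res = permanova(data, ["a"] * 6 + ["b"] * 6)
        assert res.R2 < 1e-9
        assert res.p_raw > 0.9

    def test_univariate_equals_classical_anova(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        res = permanova(y, g, method="monte_carlo", seed=0, n_permutations=9)
        f_classic = f_oneway(y[:6], y[6:12], y[12:]).statistic
        assert res.pseudo_F == pytest.approx(f_classic, abs=1e-9)

    def test_matches_scikit_bio_oracle(self):
        """Independent implementation check on the pseudo-F statistic."""
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(10)
        x = rng.normal(size=(15, 4))
        x[8:] += 0.8
        g = ["a"] * 8 + ["b"] * 7
        mine = permanova(x, g, method="monte_carlo", seed=1, n_permutations=99)
        dm = skbio.DistanceMatrix(squareform(pdist(x)))
        theirs = skbio.stats.distance.permanova(dm, g, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_monte_carlo_agrees_with_exhaustive(self):
        """9 999 random permutations vs exact enumeration, 3 binomial SEs."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=(10, 3))
        x[5:, 0] += 1.0
        g = ["a"] * 5 + ["b"] * 5  # 252 distinct arrangements
        exact = permanova(x, g, method="exact")
        mc = permanova(x, g, method="monte_carlo", seed=2, n_permutations=9_999)
        se = np.sqrt(exact.p_raw * (1 - exact.p_raw) / 10_000)
        assert abs(mc.p_raw - exact.p_raw) < 3 * se + 1e-4

    def test_r2_invariant_to_feature_rotation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(16, 6))
        x[8:] += 0.5
        g = ["a"] * 8 + ["b"] * 8
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        r1 = permanova(x, g, method="monte_carlo", seed=3, n_permutations=9)
        r2 = permanova(x @ q, g, method="monte_carlo", seed=3, n_permutations=9)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-9)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-9)

    def test_pca_scores_give_identical_statistic(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(20, 10))
        x[10:] += 0.4
        g = ["a"] * 10 + ["b"] * 10
        scores = pca_fit(x).scores
        r_raw = permanova(x, g, method="monte_carlo", seed=4, n_permutations=9)
        r_pca = permanova(scores, g, method="monte_carlo", seed=4, n_permutations=9)
        assert r_raw.pseudo_F == pytest.approx(r_pca.pseudo_F, abs=1e-9)
        assert r_raw.R2 == pytest.approx(r_pca.R2, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(np.arange(3.0), ["a", "b", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            permanova(np.arange(4.0), ["a"] * 4)

    def test_seeded_p_reproducible(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(30, 4))
        g = ["a"] * 15 + ["b"] * 15
        p1 = permanova(x, g, method="monte_carlo", seed=7, n_permutations=199).p_raw
        p2 = permanova(x, g, method="monte_carlo", seed=7, n_permutations=199).p_raw
        assert p1 == p2
        assert p1 >= 1 / 200


class TestPairwise:
    def test_bonferroni_arithmetic(self):
        # adjusted p = m * p_raw, capped at 1; with 6 pairs the smallest
        # possible adjusted value at 999 permutations is 6 * 0.001 = 0.006
        assert 6 * (1 / (999 + 1)) == pytest.approx(0.006)
        rng = np.random.default_rng(15)
        data = np.vstack([rng.normal(loc=3 * i, size=(8, 2)) for i in range(4)])
        g = np.repeat(list("abcd"), 8)
        table = pairwise_permanova(data, g, n_permutations=999, seed=0)
        assert len(table) == 6
        for _, _, r in table:
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw), abs=1e-12)

    def test_adjust_none_and_cap(self):
        rng = np.random.default_rng(16)
        data = rng.normal(size=(30, 2))
        g = np.repeat(list("abcde"), 6)
        none_tab = pairwise_permanova(data, g, n_permutations=49, seed=1,
                                      adjust="none")
        bon_tab = pairwise_permanova(data, g, n_permutations=49, seed=1)
        for (_, _, rn), (_, _, rb) in zip(none_tab, bon_tab):
            assert rn.p_adjusted == rn.p_raw
            assert rb.p_adjusted <= 1.0

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(17)
        data = np.vstack([rng.normal(loc=i, size=(6, 3)) for i in range(3)])
        g = np.repeat(list("abc"), 6)
        holm = pairwise_permanova(data, g, n_permutations=99, seed=2, adjust="holm")
        bon = pairwise_permanova(data, g, n_permutations=99, seed=2)
        for (_, _, rh), (_, _, rb) in zip(holm, bon):
            assert rh.p_adjusted <= rb.p_adjusted + 1e-12


class TestSizeTests:
    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(18)
        sizes = np.concatenate((1 + rng.normal(size=6, scale=1e-4),
                                2 + rng.normal(size=6, scale=1e-4)))
        table = size_group_tests(sizes, ["a"] * 6 + ["b"] * 6)
        assert table[0][2] < 1e-3

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(19)
        sizes = rng.uniform(1, 2, size=14)
        g1 = ["a"] * 7 + ["b"] * 7
        g2 = ["b"] * 7 + ["a"] * 7
        p1 = size_group_tests(sizes, g1)[0][2]
        p2 = size_group_tests(sizes, g2)[0][2]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_direction_reported(self):
        rng = np.random.default_rng(20)
        sizes = np.concatenate((rng.normal(1, 0.01, 5), rng.normal(3, 0.01, 5)))
        _, _, _, mean_a, mean_b = size_group_tests(sizes, ["a"] * 5 + ["b"] * 5)[0]
        assert mean_a < mean_b


class TestAllometry:
    def test_identical_shapes_r2_zero(self):
        base = np.random.default_rng(21).normal(size=(1, 20))
        coords = np.repeat(base, 10, axis=0)
        sizes = np.linspace(1, 5, 10)
        res = shape_size_regression(coords, sizes, n_permutations=19, seed=0)
        assert res.R2 == pytest.approx(0.0, abs=1e-9)

    def test_pure_allometry_r2_one(self):
        rng = np.random.default_rng(22)
        direction = rng.normal(size=20)
        sizes = np.exp(rng.uniform(0, 1, size=15))
        coords = np.outer(np.log(sizes), direction) + rng.normal(size=(1, 20))
        res = shape_size_regression(coords, sizes, n_permutations=99, seed=1)
        assert res.R2 == pytest.approx(1.0, abs=1e-9)
        assert res.p_perm <= 0.05

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(23)
        sizes = np.exp(rng.uniform(0, 1, size=30))
        coords = (np.outer(np.log(sizes), rng.normal(size=12))
                  + rng.normal(size=(30, 12), scale=0.5))
        res = shape_size_regression(coords, sizes, n_permutations=19, seed=2)
        # independent oracle: per-column OLS fitted values
        x = np.log(sizes)
        xc = x - x.mean()
        yc = coords - coords.mean(axis=0)
        beta = np.linalg.lstsq(xc[:, None], yc, rcond=None)[0]
        fitted = xc[:, None] @ beta
        r2_oracle = (fitted**2).sum() / (yc**2).sum()
        assert res.R2 == pytest.approx(r2_oracle, abs=1e-9)

    def test_constant_sizes_rejected(self):
        with pytest.raises(ValueError):
            shape_size_regression(np.random.default_rng(0).normal(size=(5, 4)),
                                  np.ones(5))


def test_significance_star_tiers():
    assert significance_stars(0.004) == "***"
    assert significance_stars(0.006) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == ""
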