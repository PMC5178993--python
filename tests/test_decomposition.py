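import numpy as np
import pytest

from metapheno.decomposition import (
    amari_index,
    choose_k_cv,
    fastica,
    orient_and_order,
    pca,
    standardize,
)
from metapheno.errors import ConvergenceError, ValidationError


class TestStandardize:
    def test_hand_computed(self):
        Xs, center, scale = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            Xs[:, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )
        assert center[0] == 2.0

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        Xs, _, _ = standardize(X)
        Xs2, _, _ = standardize(Xs)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValidationError, match="tA"):
            standardize(X, trait_names=["tA", "tB"])


class TestPca:
    def test_k_all_gives_m_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 27))
        Xs, _, _ = standardize(X)
        d = pca(Xs, k="all")
        assert d.k == 27

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=300)
        Xs, _, _ = standardize(np.column_stack([a, 2 * a + 1]))
        d = pca(Xs, k=2)
        assert d.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_explained_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10_000, 5))
        Xs, _, _ = standardize(X)
        d = pca(Xs, k="all")
        np.testing.assert_allclose(d.explained_variance, 0.2, rtol=0.05)

    def test_rows_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(4)
        Xs, _, _ = standardize(rng.normal(size=(150, 6)) @ rng.normal(size=(6, 6)))
        d = pca(Xs, k="all")
        np.testing.assert_allclose(d.weights @ d.weights.T, np.eye(6), atol=1e-10)
        assert np.all(np.diff(d.explained_variance) <= 1e-12)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(5)
        Xs, _, _ = standardize(rng.normal(size=(80, 5)))
        d = pca(Xs, k="all")
        np.testing.assert_allclose(d.scores @ d.weights, Xs, atol=1e-8)

    def test_k_too_large(self):
        Xs = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValidationError):
            pca(Xs, k=4)


class TestChooseKCv:
    def test_three_factor_recovery(self):
        rng = np.random.default_rng(6)
        n, m, q = 500, 10, 3
        X = rng.laplace(size=(n, q)) @ rng.normal(size=(q, m))
        X += 0.2 * rng.normal(size=(n, m))
        Xs, _, _ = standardize(X)
        k, press = choose_k_cv(Xs, k_max=8, n_folds=5, seed=0)
        assert k == 3
        assert press[2] == press.min()

    def test_pure_noise_curve(self):
        rng = np.random.default_rng(7)
        Xs, _, _ = standardize(rng.normal(size=(300, 8)))
        k, press = choose_k_cv(Xs, k_max=6, n_folds=5, seed=1)
        # isotropic noise: either k=1 wins or the curve never improves later
        assert k == 1 or np.all(np.diff(press[k - 1 :]) >= 0)

    def test_same_seed_identical_curve(self):
        rng = np.random.default_rng(8)
        Xs, _, _ = standardize(rng.normal(size=(100, 6)))
        _, p1 = choose_k_cv(Xs, k_max=4, seed=5)
        _, p2 = choose_k_cv(Xs, k_max=4, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_k_max_bound(self):
        Xs = np.random.default_rng(0).normal(size=(50, 4))
        with pytest.raises(ValidationError):
            choose_k_cv(Xs, k_max=4)


def two_source_fixture(seed, n=5000):
    rng = np.random.default_rng(seed)
    S = np.column_stack(
        [rng.uniform(-1, 1, size=n), rng.uniform(-1, 1, size=n)]
    )
    A = np.array([[1.0, 0.5], [0.5, 1.0]])
    return S, A, S @ A


def estimated_unmixing(Xs, d):
    """Unmixing in standardized-trait coordinates: scores = Xs @ U."""
    U, *_ = np.linalg.lstsq(Xs, d.scores, rcond=None)
    return U.T


class TestFastica:
    def test_two_source_recovery(self):
        S, A, X = two_source_fixture(seed=10)
        Xs, _, scale = standardize(X)
        d = fastica(Xs, k=2, seed=0)
        A_std = A / scale[None, :]  # mixing into standardized coordinates
        assert amari_index(estimated_unmixing(Xs, d), A_std.T) < 0.05

    def test_same_seed_identical(self):
        _, _, X = two_source_fixture(seed=11, n=2000)
        Xs, _, _ = standardize(X)
        d1 = fastica(Xs, k=2, seed=3)
        d2 = fastica(Xs, k=2, seed=3)
        np.testing.assert_array_equal(d1.weights, d2.weights)

    def test_failure_path_raises_after_restarts(self):
        rng = np.random.default_rng(12)
        Xs, _, _ = standardize(rng.normal(size=(500, 3)))
        with pytest.raises(ConvergenceError):
            fastica(Xs, k=3, seed=0, max_iter=2, tol=1e-12, n_restarts=2)

    def test_score_columns_unit_variance_uncorrelated(self):
        _, _, X = two_source_fixture(seed=13, n=3000)
        Xs, _, _ = standardize(X)
        d = fastica(Xs, k=2, seed=1)
        np.testing.assert_allclose(d.scores.std(axis=0, ddof=0), 1.0, atol=1e-8)
        np.testing.assert_allclose(d.scores.mean(axis=0), 0.0, atol=1e-8)
        r = np.corrcoef(d.scores.T)[0, 1]
        assert abs(r) < 1e-6

    def test_ica_residual_equals_pca_residual(self):
        rng = np.random.default_rng(14)
        X = rng.laplace(size=(800, 6)) @ rng.normal(size=(6, 6))
        Xs, _, _ = standardize(X)
        k = 3
        d_ica = fastica(Xs, k=k, seed=2)
        d_pca = pca(Xs, k=k)
        res_ica = np.linalg.norm(Xs - d_ica.scores @ d_ica.weights)
        res_pca = np.linalg.norm(Xs - d_pca.scores @ d_pca.weights)
        assert res_ica == pytest.approx(res_pca, rel=1e-8)

    def test_exp_contrast_also_recovers(self):
        S, A, X = two_source_fixture(seed=15)
        Xs, _, scale = standardize(X)
        d = fastica(Xs, k=2, seed=0, contrast="exp")
        A_std = A / scale[None, :]
        assert amari_index(estimated_unmixing(Xs, d), A_std.T) < 0.05

    def test_median_amari_over_seeds(self):
        vals = []
        for seed in range(20):
            S, A, X = two_source_fixture(seed=100 + seed)
            Xs, _, scale = standardize(X)
            d = fastica(Xs, k=2, seed=seed)
            vals.append(
                amari_index(estimated_unmixing(Xs, d), (A / scale[None, :]).T)
            )
        assert np.median(vals) < 0.05

    def test_orientation_makes_result_seed_invariant(self):
        S, A, X = two_source_fixture(seed=16)
        Xs, _, _ = standardize(X)
        d1 = orient_and_order(fastica(Xs, k=2, seed=1))
        d2 = orient_and_order(fastica(Xs, k=2, seed=2))
        np.testing.assert_allclose(d1.weights, d2.weights, atol=1e-4)


class TestOrientAndOrder:
    def _toy(self):
        rng = np.random.default_rng(17)
        X = rng.laplace(size=(500, 3)) @ rng.normal(size=(3, 3))
        Xs, _, _ = standardize(X)
        return fastica(Xs, k=3, seed=0)

    def test_sign_rule(self):
        d = orient_and_order(self._toy())
        for i in range(d.k):
            j = np.argmax(np.abs(d.weights[i]))
            assert d.weights[i, j] > 0

    def test_idempotent(self):
        d1 = orient_and_order(self._toy())
        d2 = orient_and_order(d1)
        np.testing.assert_array_equal(d1.weights, d2.weights)
        np.testing.assert_array_equal(d1.scores, d2.scores)

    def test_pca_order_unchanged(self):
        rng = np.random.default_rng(18)
        Xs, _, _ = standardize(rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4)))
        d = pca(Xs, k="all")
        d2 = orient_and_order(d)
        np.testing.assert_allclose(d2.explained_variance, d.explained_variance)

    def test_labels_assigned_after_sort(self):
        d = orient_and_order(self._toy())
        assert d.component_labels == ["C1", "C2", "C3"]
        assert np.all(np.diff(d.explained_variance) <= 1e-12)

    def test_scores_flip_with_weights(self):
        d0 = self._toy()
        d = orient_and_order(d0)
        # reconstruction is preserved by sign flips and reordering
        np.testing.assert_allclose(
            d.scores @ d.weights, d0.scores @ d0.weights, atol=1e-10
        )


class TestSklearnCrossCheck:
    """Independent-oracle comparison against scikit-learn."""

    def test_pca_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(30)
        X = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        Xs, _, _ = standardize(X)
        d = pca(Xs, k=4)
        sk = SkPCA(n_components=4).fit(Xs)
        np.testing.assert_allclose(
            d.explained_variance, sk.explained_variance_ratio_, rtol=1e-6
        )
        for i in range(4):
            dot = abs(np.dot(d.weights[i], sk.components_[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_fastica_sources_match_sklearn(self):
        from sklearn.decomposition import FastICA as SkICA

        S, A, X = two_source_fixture(seed=31)
        Xs, _, _ = standardize(X)
        d = fastica(Xs, k=2, seed=0)
        sk = SkICA(
            n_components=2, whiten="unit-variance", random_state=0,
            max_iter=1000,
        )
        S_sk = sk.fit_transform(Xs)
        # same sources up to permutation and sign
        C = np.corrcoef(d.scores.T, S_sk.T)[:2, 2:]
        best = np.max(np.abs(C), axis=1)
        np.testing.assert_allclose(best, 1.0, atol=1e-3)
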