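import numpy as np
import pytest
from scipy import stats

from metapheno.data_io import PedigreeRecord, PedigreeTable
from metapheno.errors import ValidationError
from metapheno.kinship import KinshipMatrix, kinship_matrix
from metapheno.synthetic_data import drop_genotypes, simulate_pedigrees
from metapheno.varcomp_gwas import (
    KinshipEigen,
    assoc_snp,
    fit_polygenic,
    gwas,
    heritability,
)

from conftest import geno


def identity_kinship(n):
    return KinshipMatrix(0.5 * np.eye(n), [f"i{i}" for i in range(n)])


def ols_loglik(y, X):
    """Closed-form ML Gaussian linear-model loglik (the K=I oracle)."""
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    n = y.size
    s2 = (r**2).mean()
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


class TestFitPolygenic:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = 40
            C = rng.normal(size=(n, 2))
            y = rng.normal(size=n) + C @ rng.normal(size=2)
            fit = fit_polygenic(y, C, identity_kinship(n))
            X = np.column_stack([np.ones(n), C])
            assert fit.loglik == pytest.approx(ols_loglik(y, X), abs=1e-6)
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_unrelated_no_genetic_variance(self):
        # diagonal kinship: sigma_g2 and sigma_e2 are exchangeable, the
        # optimizer settles on the h=0 boundary
        rng = np.random.default_rng(1)
        n = 200
        y = rng.normal(size=n)
        fit = fit_polygenic(y, None, identity_kinship(n))
        assert fit.h2 == 0.0

    def test_h2_recovery_family_design(self):
        ped = simulate_pedigrees(21, 19, 3, seed=2)
        K = kinship_matrix(ped)
        eig = KinshipEigen(K)
        n = len(ped)
        L = np.linalg.cholesky(K.additive + 1e-9 * np.eye(n))
        rng = np.random.default_rng(3)
        h2 = 0.5
        ests = [
            fit_polygenic(
                np.sqrt(h2) * (L @ rng.standard_normal(n))
                + np.sqrt(1 - h2) * rng.standard_normal(n),
                None,
                eig,
            ).h2
            for _ in range(60)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.06)

    def test_null_h2_small(self):
        ped = simulate_pedigrees(21, 19, 3, seed=4)
        eig = KinshipEigen(kinship_matrix(ped))
        rng = np.random.default_rng(5)
        small = sum(
            fit_polygenic(rng.standard_normal(len(ped)), None, eig).h2 < 0.05
            for _ in range(60)
        )
        assert small >= 0.8 * 60

    def test_singular_design_rejected(self):
        n = 30
        C = np.ones((n, 1))  # collinear with the intercept
        y = np.random.default_rng(6).normal(size=n)
        with pytest.raises(ValidationError, match="singular"):
            fit_polygenic(y, C, identity_kinship(n))

    def test_variance_components_nonnegative(self):
        ped = simulate_pedigrees(5, 12, 3, seed=7)
        eig = KinshipEigen(kinship_matrix(ped))
        rng = np.random.default_rng(8)
        fit = fit_polygenic(rng.standard_normal(len(ped)), None, eig)
        assert fit.sigma_g2 >= 0
        assert fit.sigma_e2 > 0


class TestHeritability:
    def test_h2r_definition(self):
        ped = simulate_pedigrees(8, 15, 3, seed=9)
        K = kinship_matrix(ped)
        n = len(ped)
        L = np.linalg.cholesky(K.additive + 1e-9 * np.eye(n))
        rng = np.random.default_rng(10)
        y = 0.8 * (L @ rng.standard_normal(n)) + 0.6 * rng.standard_normal(n)
        res = heritability(y, None, K, label="C1")
        assert res.h2r == pytest.approx(
            res.sigma_g2 / (res.sigma_g2 + res.sigma_e2), abs=1e-10
        )
        assert res.metaphenotype_label == "C1"

    def test_zero_lrt_gives_half(self):
        # diagonal kinship makes the boundary fit optimal: LRT is 0
        rng = np.random.default_rng(11)
        n = 100
        res = heritability(rng.standard_normal(n), None, identity_kinship(n))
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(0.5, abs=1e-6)

    def test_boundary_mixture_pvalue(self):
        ped = simulate_pedigrees(10, 15, 3, seed=12)
        K = kinship_matrix(ped)
        n = len(ped)
        L = np.linalg.cholesky(K.additive + 1e-9 * np.eye(n))
        rng = np.random.default_rng(13)
        y = 0.9 * (L @ rng.standard_normal(n)) + 0.4 * rng.standard_normal(n)
        res = heritability(y, None, K)
        if res.lrt_stat > 0:
            assert res.p_value == pytest.approx(
                0.5 * stats.chi2.sf(res.lrt_stat, 1), rel=1e-10
            )


@pytest.fixture(scope="module")
def family_data():
    ped = simulate_pedigrees(10, 15, 3, seed=14)
    K = kinship_matrix(ped)
    G = drop_genotypes(ped, 5, 0.3, seed=15)
    n = len(ped)
    L = np.linalg.cholesky(K.additive + 1e-9 * np.eye(n))
    return ped, K, G, L


@pytest.fixture(scope="module")
def gwas_run():
    ped = simulate_pedigrees(8, 15, 3, seed=21)
    K = kinship_matrix(ped)
    G = drop_genotypes(ped, 6, 0.3, seed=22)
    n = len(ped)
    rng = np.random.default_rng(23)
    M = rng.standard_normal((n, 2))
    return gwas(M, G, None, K, alpha=0.05)


class TestAssocSnp:
    def test_chi2_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_power_on_causal_snp(self, family_data):
        ped, K, G, L = family_data
        rng = np.random.default_rng(16)
        g = G.values[:, 0]
        gs = (g - g.mean()) / g.std()
        n = len(ped)
        y = np.sqrt(0.3) * gs + np.sqrt(0.7) * rng.standard_normal(n)
        r = assoc_snp(y, None, K, g, snp_id="snp0001")
        assert r.p_raw < 1e-6
        assert r.beta_snp != 0

    def test_monomorphic_untestable(self, family_data):
        ped, K, G, _ = family_data
        n = len(ped)
        g = np.zeros(n)
        r = assoc_snp(np.random.default_rng(17).normal(size=n), None, K, g)
        assert not r.testable
        assert np.isnan(r.p_raw)

    def test_missing_genotypes_complete_case(self, family_data):
        ped, K, G, L = family_data
        rng = np.random.default_rng(18)
        n = len(ped)
        g = G.values[:, 1].copy()
        g[:10] = np.nan
        y = rng.standard_normal(n)
        r = assoc_snp(y, None, K, g)
        assert r.n_used == n - 10

    def test_affine_invariance_of_lrt(self, family_data):
        ped, K, G, L = family_data
        rng = np.random.default_rng(19)
        n = len(ped)
        y = 0.6 * (L @ rng.standard_normal(n)) + 0.8 * rng.standard_normal(n)
        g = G.values[:, 2]
        r1 = assoc_snp(y, None, K, g)
        r2 = assoc_snp(5.0 * y - 7.0, None, K, g)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-5)

    def test_heritability_lrt_affine_invariance(self, family_data):
        ped, K, G, L = family_data
        rng = np.random.default_rng(20)
        n = len(ped)
        y = 0.6 * (L @ rng.standard_normal(n)) + 0.8 * rng.standard_normal(n)
        r1 = heritability(y, None, K)
        r2 = heritability(-3.0 * y + 11.0, None, K)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-5)


class TestGwas:
    def test_bonferroni_multiplier(self, gwas_run):
        results = gwas_run
        n_tests = sum(r.testable for r in results)
        assert n_tests == 12
        for r in results:
            if r.testable:
                assert r.p_adjusted == pytest.approx(
                    min(1.0, r.p_raw * n_tests), rel=1e-12
                )
                assert r.p_adjusted >= r.p_raw

    def test_cap_at_one(self, gwas_run):
        big = [r for r in gwas_run if r.testable and r.p_raw > 1.0 / 12]
        assert big, "fixture should contain non-significant pairs"
        assert all(r.p_adjusted == 1.0 for r in big)

    def test_every_pair_present(self, gwas_run):
        assert len(gwas_run) == 12
        labels = {r.metaphenotype_label for r in gwas_run}
        assert labels == {"C1", "C2"}

    def test_marker_metadata_attached(self, gwas_run):
        r = gwas_run[0]
        assert r.chromosome == "1"
        assert r.position > 0
        assert 0 <= r.maf <= 0.5
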