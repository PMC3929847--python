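"""Tests of the correlation structures, copula sampler and experiment loops."""

import numpy as np
import pytest
from scipy import stats

from lancaster import (
    LDConfig,
    ScenarioSpec,
    SigmaSpec,
    WeightVector,
    build_sigma,
    copula_rho_matrix,
    copula_transformed_cov,
    disease_model,
    gamma_transform,
    qq_comparison,
    rejection_rate_experiment,
    sample_correlated_pvalues,
)
from lancaster.harness import _copula_pvalue_draws


class TestBuildSigma:
    def test_block_fixed_structure(self):
        spec = SigmaSpec(kind="block_fixed", rho=0.3, n_blocks=20, block_size=5)
        sigma = build_sigma(spec)
        assert sigma.shape == (100, 100)
        assert np.all(np.diag(sigma) == 1.0)
        assert sigma[0, 4] == 0.3 and sigma[0, 5] == 0.0
        assert np.array_equal(sigma, sigma.T)

    def test_compound_symmetry_spectrum(self):
        sigma = build_sigma(SigmaSpec(kind="block_fixed", rho=0.6, n_blocks=1, block_size=5))
        eig = np.sort(np.linalg.eigvalsh(sigma))
        assert eig[-1] == pytest.approx(1 + 4 * 0.6)
        assert eig[0] == pytest.approx(1 - 0.6)

    def test_pd_bound_enforced(self):
        with pytest.raises(ValueError):
            SigmaSpec(kind="block_fixed", rho=-0.3, block_size=5)

    @pytest.mark.parametrize("kind", ["block_beta", "block_uniform", "random_pd"])
    def test_random_kinds_are_correlation_matrices(self, kind):
        spec = SigmaSpec(kind=kind, n_blocks=4, block_size=5)
        sigma = build_sigma(spec, seed=1)
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma).min() > 0
        assert np.allclose(sigma, sigma.T)

    def test_random_pd_varies_with_seed(self):
        spec = SigmaSpec(kind="random_pd", n_blocks=2, block_size=5)
        assert not np.allclose(build_sigma(spec, seed=1), build_sigma(spec, seed=2))


class TestCopulaSampler:
    def test_marginals_uniform_under_identity(self):
        sigma = np.eye(8)
        draws = _copula_pvalue_draws(sigma, 500, np.random.default_rng(2))
        assert stats.kstest(draws.ravel(), "uniform").pvalue > 0.01

    def test_marginals_uniform_under_correlation(self):
        sigma = build_sigma(SigmaSpec(kind="block_fixed", rho=0.5, n_blocks=2, block_size=5))
        draws = _copula_pvalue_draws(sigma, 500, np.random.default_rng(3))
        for j in range(10):
            assert stats.kstest(draws[:, j], "uniform").pvalue > 0.001

    def test_fixed_seed_reproducible(self):
        sigma = np.eye(4)
        a = sample_correlated_pvalues(sigma, seed=4)
        b = sample_correlated_pvalues(sigma, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_non_pd_sigma_surfaces_error(self):
        sigma = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            sample_correlated_pvalues(sigma, seed=0)


class TestCopulaCovOracle:
    def test_zero_correlation_gives_zero_covariance(self):
        assert copula_transformed_cov(0.0, 2.0, 2.0) == 0.0

    def test_near_unit_correlation_approaches_full_variance(self):
        # perfectly dependent chi2_2 values: cov -> Var(chi2_2) = 4
        assert copula_transformed_cov(0.9999, 2.0, 2.0) == pytest.approx(4.0, abs=0.05)

    def test_quadrature_matches_monte_carlo(self):
        r, w = 0.45, 2.0
        quad = copula_transformed_cov(r, w, w)
        rng = np.random.default_rng(5)
        n = 400_000
        z1 = rng.standard_normal(n)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
        x1 = gamma_transform(stats.norm.sf(z1), w)
        x2 = gamma_transform(stats.norm.sf(z2), w)
        mc = np.cov(x1, x2, ddof=1)[0, 1]
        se = np.std((x1 - x1.mean()) * (x2 - x2.mean())) / np.sqrt(n)
        assert quad == pytest.approx(mc, abs=3 * se)

    def test_rho_matrix_layout(self):
        sigma = build_sigma(SigmaSpec(kind="block_fixed", rho=0.3, n_blocks=1, block_size=3))
        w = WeightVector.from_array([2.0, 2.0, 2.0])
        rho = copula_rho_matrix(sigma, w)
        assert np.allclose(np.diag(rho), 4.0)
        assert rho[0, 1] == rho[1, 2] == rho[0, 2]  # common block correlation
        assert rho[0, 1] > 0


class TestQQComparison:
    def test_independent_case_all_methods_track_empirical(self):
        spec = SigmaSpec(kind="block_fixed", rho=0.0, n_blocks=2, block_size=5)
        w = WeightVector.from_array(np.full(10, 2.0))
        df = qq_comparison(spec, w, n_draws=100_000, seed=6)
        for col in ("naive", "TA", "TB", "TC", "TD", "TE"):
            slope = np.sum(df[col] * df["empirical"]) / np.sum(df["empirical"] ** 2)
            assert 0.97 < slope < 1.03, col

    def test_naive_reference_underdisperses_under_correlation(self):
        """With block correlation 0.3 the naive chi-square reference is less
        dispersed than T, so its 95th percentile is exceeded more than 5% of
        the time — the inflation that motivates the adjustment."""
        spec = SigmaSpec(kind="block_fixed", rho=0.3, n_blocks=4, block_size=5)
        w = WeightVector.from_array(np.full(20, 2.0))
        rng = np.random.default_rng(7)
        sigma = build_sigma(spec, rng)
        p = _copula_pvalue_draws(sigma, 20_000, rng)
        T = gamma_transform(p, w.w[None, :]).sum(axis=1)
        naive_q95 = stats.chi2.ppf(0.95, np.sum(w.w))
        assert (T > naive_q95).mean() > 0.06
        # while the moment-adjusted quantile restores the nominal level
        df = qq_comparison(spec, w, n_draws=20_000, seed=7, probs=[0.95])
        assert (T > df["TA"].iloc[0]).mean() == pytest.approx(0.05, abs=0.012)

    def test_requires_enough_draws(self):
        spec = SigmaSpec(kind="block_fixed", rho=0.0, n_blocks=1, block_size=2)
        w = WeightVector.from_array([2.0, 2.0])
        with pytest.raises(ValueError):
            qq_comparison(spec, w, n_draws=10)


class TestRejectionRateExperiment:
    def test_single_replicate_degenerate_run(self):
        spec = ScenarioSpec(
            ld_config=LDConfig(n_subjects=100, D=0.15),
            model=disease_model("I", 0.0),
            reps=1,
            m_perm=20,
            seed=8,
        )
        out = rejection_rate_experiment(spec)
        assert out["n_ok"] + out["n_failed"] == 1
        assert all(rate in (0.0, 1.0) for rate in out["rates"].values())

    def test_order_invariant_given_master_seed(self):
        spec = ScenarioSpec(
            ld_config=LDConfig(n_subjects=100, D=0.15),
            model=disease_model("I", 0.0),
            reps=5,
            m_perm=20,
            seed=9,
        )
        a = rejection_rate_experiment(spec)
        b = rejection_rate_experiment(spec)
        assert a["rates"] == b["rates"]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec(
                ld_config=LDConfig(n_subjects=10, D=0.0),
                model=disease_model("I", 0.0),
                reps=0,
            )
        with pytest.raises(ValueError):
            ScenarioSpec(
                ld_config=LDConfig(n_subjects=10, D=0.0),
                model=disease_model("I", 0.0),
                alpha=1.5,
            )
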