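"""Variance-component score test: kernel normalization, null model,
low-rank statistic/weights against dense oracles, and mixture-of-chi-square
tail probabilities against exact quantiles, Monte Carlo and permutations."""

import numpy as np
import pytest
from scipy import stats

from histoqtl.score_test import (
    DegenerateVariantError,
    ScoreTest,
    cosine_normalize,
    davies_pvalue,
    fit_null,
    liu_pvalue,
    mixture_pvalue,
    null_weights,
    score_statistic,
)
from histoqtl.score_test import test_variant as single_variant_test


def _random_instance(rng, n=120, L=8, k=3):
    F = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    X = rng.standard_normal((n, L))
    g = rng.binomial(2, 0.3, size=n).astype(float)
    return g, F, cosine_normalize(X)


def _dense_weights(g, F, Xn):
    """Dense N x N oracle for the null mixture weights."""
    n = len(g)
    M = np.eye(n) - F @ np.linalg.pinv(F)
    r = M @ g
    sigma2 = (r @ r) / (n - np.linalg.matrix_rank(F))
    lam = np.linalg.eigvalsh(M @ Xn.kernel() @ M) * sigma2
    lam = lam[lam > 1e-10 * lam.max()]
    return r, sigma2, np.sort(lam)[::-1]


class TestCosineNormalize:
    def test_three_four_five_triangle(self):
        out = cosine_normalize(np.array([[3.0, 4.0], [1.0, 0.0]]))
        assert np.allclose(out.values[0], [0.6, 0.8])

    def test_kernel_entries_for_identical_and_orthogonal_rows(self):
        Xn = cosine_normalize(np.array([[2.0, 0.0], [5.0, 0.0], [0.0, 1.0]]))
        K = Xn.kernel()
        assert K[0, 1] == pytest.approx(1.0)
        assert K[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_zero_row_names_the_sample(self):
        with pytest.raises(ValueError, match="badsample"):
            cosine_normalize(np.array([[1.0, 0.0], [0.0, 0.0]]), ids=["ok", "badsample"])


class TestFitNull:
    def test_intercept_only_is_centering(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        null = fit_null(g, np.ones((50, 1)))
        assert np.allclose(null.residuals, g - g.mean())
        assert null.sigma2 == pytest.approx(np.sum((g - g.mean()) ** 2) / 49)

    def test_alpha_matches_normal_equations(self, rng):
        g, F, _ = _random_instance(rng)
        null = fit_null(g, F)
        expect = np.linalg.solve(F.T @ F, F.T @ g)
        assert np.allclose(null.alpha_hat, expect, atol=1e-10)
        assert np.allclose(F.T @ null.residuals, 0.0, atol=1e-8 * np.linalg.norm(g))

    def test_genotype_in_covariate_span_is_degenerate(self):
        F = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DegenerateVariantError):
            fit_null(F @ np.array([1.0, 0.5]), F)


class TestScoreStatistic:
    def test_one_hot_rows_give_residual_norm(self, rng):
        n = 30
        g = rng.binomial(2, 0.3, n).astype(float)
        null = fit_null(g, np.ones((n, 1)))
        Xn = cosine_normalize(np.eye(n))
        assert score_statistic(null, Xn) == pytest.approx(null.residuals @ null.residuals)

    def test_constant_kernel_annihilated_by_intercept(self, rng):
        n = 30
        g = rng.binomial(2, 0.3, n).astype(float)
        null = fit_null(g, np.ones((n, 1)))
        Xn = cosine_normalize(np.tile([1.0, 2.0], (n, 1)))
        assert score_statistic(null, Xn) == pytest.approx(0.0, abs=1e-18)

    def test_matches_dense_kernel_quadratic_form(self, rng):
        g, F, Xn = _random_instance(rng)
        null = fit_null(g, F)
        Q = score_statistic(null, Xn)
        dense = null.residuals @ Xn.kernel() @ null.residuals
        assert Q == pytest.approx(dense, rel=1e-8)


class TestNullWeights:
    def test_matches_dense_eigendecomposition(self, rng):
        g, F, Xn = _random_instance(rng)
        null = fit_null(g, F)
        lam = null_weights(null, Xn)
        _, _, lam_dense = _dense_weights(g, F, Xn)
        assert np.allclose(lam, lam_dense[: len(lam)], rtol=1e-8)

    def test_orthonormal_columns_orthogonal_to_covariates(self, rng):
        # columns chosen orthonormal and orthogonal to the intercept
        n, L = 40, 4
        raw = rng.standard_normal((n, L))
        raw -= raw.mean(axis=0)
        basis, _ = np.linalg.qr(raw)
        g = rng.binomial(2, 0.3, n).astype(float)
        null = fit_null(g, np.ones((n, 1)))
        # rows of this matrix are not unit norm, so bypass cosine scaling:
        from histoqtl.score_test import NormalizedEmbedding
        lam = null_weights(null, NormalizedEmbedding(values=basis))
        assert np.allclose(lam, null.sigma2, rtol=1e-8)


class TestDaviesPvalue:
    def test_chi_square_quantiles(self):
        p1, c1 = davies_pvalue(stats.chi2.isf(0.05, 1), [1.0])
        p2, c2 = davies_pvalue(stats.chi2.isf(0.05, 2), [1.0, 1.0])
        assert c1 and c2
        assert p1 == pytest.approx(0.05, abs=1e-9)
        assert p2 == pytest.approx(0.05, abs=1e-9)

    def test_two_component_mixture_matches_monte_carlo(self, rng):
        draws = 2.0 * rng.chisquare(1, 10_000_000) + rng.chisquare(1, 10_000_000)
        mc = float(np.mean(draws > 8.0))
        ci = 2.58 * np.sqrt(mc * (1 - mc) / draws.size)
        p, converged = davies_pvalue(8.0, [2.0, 1.0])
        assert converged
        assert abs(p - mc) < ci

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            davies_pvalue(1.0, [0.0, 0.0])

    def test_far_tail_flags_fallback(self):
        p, converged = davies_pvalue(500.0, [2.0, 1.0])
        assert not converged


class TestLiuPvalue:
    def test_single_weight_is_exact_chi_square(self):
        q = stats.chi2.isf(0.02, 1) * 1.7
        assert liu_pvalue(q, [1.7]) == pytest.approx(davies_pvalue(q, [1.7])[0], abs=1e-9)

    def test_equal_weights_exact(self):
        assert liu_pvalue(stats.chi2.isf(0.05, 3), [1.0, 1.0, 1.0]) == pytest.approx(0.05, abs=1e-9)

    def test_moderate_tail_against_monte_carlo(self, rng):
        lam = np.array([3.0, 1.0, 0.5])
        draws = lam @ rng.chisquare(1, (3, 20_000_000))
        q = 45.0
        mc = float(np.mean(draws > q))  # ~1e-4 scale
        assert liu_pvalue(q, lam) == pytest.approx(mc, rel=0.2)

    def test_far_tail_within_20pct_of_inversion(self):
        # Davies converges here and is independently Monte-Carlo verified
        lam = [3.0, 1.0, 0.5]
        q = 55.0  # p ~ 2.5e-5
        p_davies, converged = davies_pvalue(q, lam)
        assert converged
        assert liu_pvalue(q, lam) == pytest.approx(p_davies, rel=0.2)


class TestTestVariant:
    def test_null_pvalues_uniform(self, null_cohort):
        cfg, _, F, E = null_cohort
        engine = ScoreTest(F, cosine_normalize(E))
        rng = np.random.default_rng(17)
        G = rng.binomial(2, 0.3, size=(cfg.n, 1500)).astype(float)
        p, _ = engine.pvalues(G)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_effect_is_detected(self, small_cohort):
        cfg, g, F, E = small_cohort
        res = single_variant_test(g, F, cosine_normalize(E))
        assert res.tested and res.p_value < 1e-8

    def test_matches_permutation_pvalue(self, rng):
        n, L = 200, 6
        F = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Xn = cosine_normalize(rng.standard_normal((n, L)))
        g = rng.binomial(2, 0.25, n).astype(float)
        engine = ScoreTest(F, Xn)
        q_obs = np.divide(*engine.statistics(g))
        n_perm = 20_000
        q_perm = np.empty(n_perm)
        for b in range(n_perm):
            qq, ss = engine.statistics(g[rng.permutation(n)])
            q_perm[b] = qq[0] / ss[0]
        p_perm = (1 + np.sum(q_perm >= q_obs[0])) / (n_perm + 1)
        p_analytic = engine.test(g).p_value
        ci = 2.58 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_analytic - p_perm) < max(ci, 1e-3)

    def test_degenerate_variant_flagged_untested(self):
        F = np.column_stack([np.ones(30), np.arange(30.0)])
        Xn = cosine_normalize(np.random.default_rng(0).standard_normal((30, 4)))
        res = single_variant_test(F @ np.array([2.0, 1.0]), F, Xn)
        assert not res.tested and res.method == "untested"


class TestInvariances:
    def test_location_invariance_in_covariate_span(self, rng):
        g, F, Xn = _random_instance(rng)
        engine = ScoreTest(F, Xn)
        r1 = engine.test(g)
        r2 = engine.test(g + F @ rng.standard_normal(F.shape[1]))
        assert r1.Q == pytest.approx(r2.Q, rel=1e-8, abs=1e-8)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)

    def test_scale_equivariance(self, rng):
        g, F, Xn = _random_instance(rng)
        engine = ScoreTest(F, Xn)
        r1, r2 = engine.test(g), engine.test(3.0 * g)
        assert r2.Q == pytest.approx(9.0 * r1.Q, rel=1e-10)
        assert np.allclose(r2.lambdas, 9.0 * r1.lambdas, rtol=1e-10)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-6)

    def test_pvalue_invariant_under_statistic_rescaling(self, rng):
        # any consistent rescaling of Q and the weights leaves p unchanged
        g, F, Xn = _random_instance(rng)
        null = fit_null(g, F)
        Q = score_statistic(null, Xn)
        lam = null_weights(null, Xn)
        c = 1.0 / (2.0 * null.sigma2**2)
        p1, _ = mixture_pvalue(Q, lam)
        p2, _ = mixture_pvalue(c * Q, c * lam)
        assert p1 == pytest.approx(p2, rel=1e-7)
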