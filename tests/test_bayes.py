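"""Gibbs samplers for BRR and Bayes C-pi, standardization, prior scale."""

import numpy as np
import pytest

from gepred.bayes import (BayesC, BayesianRidge, McmcConfig, PriorSpec,
                          _brr_kernel, default_marker_scale, fit_brr,
                          predict_gebv, standardize)

def _batch_se(draws, n_batches=15):
    """Monte-Carlo SE of the chain mean via batch means."""
    d = np.atleast_2d(draws.T).T
    bs = d.shape[0] // n_batches
    bm = d[:n_batches * bs].reshape(n_batches, bs, -1).mean(axis=1)
    return bm.std(axis=0, ddof=1) / np.sqrt(n_batches)


def _toy(seed, n=100, m=20, sd_beta=0.3):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    y = 2.0 + Z @ rng.normal(0, sd_beta, m) + rng.normal(0, 1.0, n)
    return y, Z


class TestStandardize:
    def test_columns_centered_and_unit_variance(self, rng):
        M = rng.binomial(2, 0.3, (50, 10)).astype(float)
        Zs, means, sds = standardize(M)
        np.testing.assert_allclose(Zs.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Zs.std(0, ddof=1), 1, atol=1e-12)

    def test_single_column_sample_sd_convention(self):
        Zs, means, sds = standardize(np.array([[0.], [1.], [2.]]))
        # sample SD (n-1) convention: sd = 1 exactly for (0,1,2)
        np.testing.assert_allclose(Zs.ravel(), [-1.0, 0.0, 1.0])
        # the population-SD convention of the same column scales by
        # sqrt(3/2): +-1.2247 -- a pure-arithmetic cross-check of the scale
        np.testing.assert_allclose(Zs.ravel() * np.sqrt(3 / 2),
                                   [-1.2247, 0, 1.2247], atol=1e-4)

    def test_idempotent_on_standardized_input(self, rng):
        M = rng.normal(size=(40, 5))
        Z1, _, _ = standardize(M)
        Z2, _, _ = standardize(Z1)
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(np.ones((10, 2)))

    def test_missing_rejected(self):
        M = np.ones((5, 1)) * np.arange(5)[:, None]
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            standardize(M)


class TestMarkerScale:
    def test_printed_formula_single_marker(self):
        prior = PriorSpec(v_a=4.2, sigma_s2_tilde=1.0)
        S2a = default_marker_scale(prior, pi=0.0, allele_freqs=[0.5])
        # sigma_tilde_a2 = 1 / (1 * 0.25) = 4; S2a = 4 * 2.2 / 4.2
        assert S2a == pytest.approx(4 * 2.2 / 4.2)
        assert S2a == pytest.approx(2.0952, abs=1e-4)

    def test_doubling_markers_halves_scale(self):
        prior = PriorSpec(v_a=4.2, sigma_s2_tilde=1.0)
        one = default_marker_scale(prior, 0.0, [0.3])
        two = default_marker_scale(prior, 0.0, [0.3, 0.3])
        assert two == pytest.approx(one / 2)

    def test_large_dof_limit(self):
        prior = PriorSpec(v_a=1e9, sigma_s2_tilde=1.0)
        S2a = default_marker_scale(prior, 0.0, [0.5])
        assert S2a == pytest.approx(4.0, rel=1e-6)

    def test_het_factor_switch(self):
        base = PriorSpec(v_a=4.2, sigma_s2_tilde=1.0)
        doubled = PriorSpec(v_a=4.2, sigma_s2_tilde=1.0, het_factor_2=True)
        assert default_marker_scale(doubled, 0.0, [0.4]) == pytest.approx(
            default_marker_scale(base, 0.0, [0.4]) / 2)

    def test_pi_one_rejected(self):
        with pytest.raises(ValueError):
            default_marker_scale(PriorSpec(sigma_s2_tilde=1.0), 1.0, [0.5])


class TestBrr:
    def test_fixed_variance_posterior_matches_closed_form_ridge(self):
        """With variances frozen, the Gibbs posterior mean is the ridge
        solution (conjugate Gaussian linear model), verified across 5 toys
        via a whitened, ESS-scaled chi-square statistic."""
        from mcmc_checks import whitened_chi2
        total, K = 0.0, 0
        for seed in range(5):
            y, Z = _toy(seed)
            n, m = Z.shape
            s2a, s2e = 0.09, 1.0
            post = BayesianRidge(y, Z).fit(
                McmcConfig(6000, 1000, 1, seed=seed + 100),
                sample_variances=False, sigma2_a=s2a, sigma2_e=s2e)
            W = np.column_stack([np.ones(n), Z])
            D = np.diag([0.0] + [s2e / s2a] * m)
            A = W.T @ W + D
            ref = np.linalg.solve(A, W.T @ y)
            draws = np.column_stack([post.mu_samples, post.effect_draws])
            chi2, k = whitened_chi2(draws, ref, np.linalg.inv(A) * s2e)
            total += chi2
            K += k
        # 3-SD band of the aggregate chi-square across all toys
        assert total < K + 3 * np.sqrt(2 * K)

    def test_null_response_gives_null_effects(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(80, 10))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        post = BayesianRidge(np.zeros(80), Z).fit(
            McmcConfig(4000, 1000, 1, seed=0),
            sample_variances=False, sigma2_a=0.1, sigma2_e=1.0)
        se = _batch_se(post.effect_draws)
        assert np.all(np.abs(post.effect_means) < 4 * np.maximum(se, 1e-6))

    def test_gebv_beats_permutation_baseline(self):
        rng = np.random.default_rng(3)
        n, m = 1000, 200
        Z = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
        Zs, mu_, sd_ = standardize(Z)
        beta = rng.normal(0, 1.0, m)
        g = Zs @ beta
        g = g / g.std()
        y = g + rng.normal(0, 1.0, n)       # h2 = 0.5, dense effects
        mc = McmcConfig(4000, 1500, 5, seed=7)
        post = fit_brr(y, Zs, mc)
        gebv = post.mu_mean + Zs @ post.effect_means
        r_true = np.corrcoef(g, gebv)[0, 1]
        post_null = fit_brr(rng.permutation(y), Zs, mc)
        gebv_null = post_null.mu_mean + Zs @ post_null.effect_means
        r_null = abs(np.corrcoef(g, gebv_null)[0, 1])
        assert r_true > 0.5
        assert r_true > r_null

    def test_seeded_chains_bit_reproducible(self):
        y, Z = _toy(1)
        mc = McmcConfig(2000, 500, 5, seed=99)
        a = BayesianRidge(y, Z).fit(mc)
        b = BayesianRidge(y, Z).fit(mc)
        np.testing.assert_array_equal(a.effect_draws, b.effect_draws)
        np.testing.assert_array_equal(a.variance_samples["sigma2_e"],
                                      b.variance_samples["sigma2_e"])

    def test_retained_draw_count(self):
        y, Z = _toy(2)
        post = BayesianRidge(y, Z).fit(McmcConfig(3000, 1000, 5, seed=0))
        assert post.retained_draw_count == (3000 - 1000) // 5


class TestBayesC:
    def test_pi_zero_reduces_to_brr_exactly(self):
        """Point mass at pi=0 makes every marker enter each sweep; the
        sampler then walks the identical Gibbs path as BRR."""
        y, Z = _toy(1, n=120, m=15)
        mc = McmcConfig(4000, 1000, 5, seed=5)
        a = BayesC(y, Z).fit(mc, prior=PriorSpec(pi_prior=0.0))
        b = BayesianRidge(y, Z).fit(mc)
        np.testing.assert_allclose(a.effect_means, b.effect_means, atol=1e-12)
        assert np.all(a.inclusion_probs == 1.0)

    def test_sparse_architecture_recovered(self):
        rng = np.random.default_rng(7)
        n, m, nq = 500, 200, 5
        Z = rng.binomial(2, rng.uniform(0.05, 0.5, m), (n, m)).astype(float)
        Zs, _, _ = standardize(Z)
        qtl = rng.choice(m, nq, replace=False)
        beta = np.zeros(m)
        beta[qtl] = rng.normal(0, 1.0, nq)
        g = Zs @ beta
        y = g + rng.normal(0, g.std(), n)
        post = BayesC(y, Zs).fit(McmcConfig(8000, 3000, 5, seed=2))
        assert np.mean(post.pi_samples) > 0.8
        null = np.delete(post.inclusion_probs, qtl)
        assert post.inclusion_probs[qtl].mean() > null.mean()

    def test_pure_noise_concentrates_pi_high(self):
        rng = np.random.default_rng(11)
        n, m = 400, 100
        Z = rng.binomial(2, 0.3, (n, m)).astype(float)
        Zs, mu_, sd_ = standardize(Z)
        y = rng.normal(0, 1.0, n)
        post = BayesC(y, Zs, transform=(mu_, sd_)).fit(
            McmcConfig(6000, 2000, 5, seed=3))
        assert np.mean(post.pi_samples) > 0.8
        gebv = predict_gebv(Z, (mu_, sd_), post)
        assert np.var(gebv) < 0.1 * np.var(y)

    def test_tiny_marker_variance_sends_gebv_to_mu(self):
        y, Z = _toy(4)
        post = BayesC(y, Z).fit(
            McmcConfig(3000, 1000, 5, seed=1),
            prior=PriorSpec(sigma_s2_tilde=1e-10))
        gebv = post.mu_mean + Z @ post.effect_means
        assert np.std(gebv) < 0.05 * np.std(y)

    def test_prior_marginal_invariant_under_gibbs(self):
        """Getting-it-right check: alternating (data | params) and the
        sampler's (params | data) updates leaves the prior marginal of
        sigma2_a invariant; compared on E[log sigma2_a]."""
        rng = np.random.default_rng(0)
        n, m = 20, 5
        Z = rng.normal(size=(n, m))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        v_a, S2_a, v_e, S2_e = 10.0, 0.5, 10.0, 1.0
        n_cycles = 4000
        mu, a = 0.0, rng.normal(0, np.sqrt(0.5), m)
        s2a = v_a * S2_a / rng.chisquare(v_a)
        s2e = v_e * S2_e / rng.chisquare(v_e)
        log_s2a = np.empty(n_cycles)
        for t in range(n_cycles):
            y = mu + Z @ a + rng.normal(0, np.sqrt(s2e), n)
            out = _brr_kernel(y, np.asfortranarray(Z), 1, 0, 1,
                              v_a, S2_a, v_e, S2_e, True, s2a, s2e,
                              mu, a, int(rng.integers(2**31)))
            mu, a, s2a, s2e = out[5], out[6], out[7], out[8]
            log_s2a[t] = np.log(s2a)
        prior_draws = np.log(v_a * S2_a / rng.chisquare(v_a, 200_000))
        se_chain = _batch_se(log_s2a[500:])[0]
        se_prior = prior_draws.std() / np.sqrt(len(prior_draws))
        diff = abs(log_s2a[500:].mean() - prior_draws.mean())
        assert diff < 4 * np.hypot(se_chain, se_prior)


class TestPredict:
    def test_zero_effects_constant_prediction(self):
        post = BayesianRidge(*_toy(0)).fit(
            McmcConfig(200, 100, 1, seed=0), sample_variances=False,
            sigma2_a=1.0, sigma2_e=1.0)
        post.effect_means[:] = 0.0
        G = np.random.default_rng(0).binomial(2, 0.4, (5, 20)).astype(float)
        pred = predict_gebv(G, (G.mean(0), np.maximum(G.std(0, ddof=1), 1)),
                            post)
        np.testing.assert_allclose(pred, post.mu_mean)

    def test_training_row_reproduces_fitted_value(self):
        rng = np.random.default_rng(8)
        Graw = rng.binomial(2, 0.4, (30, 10)).astype(float)
        Zs, means, sds = standardize(Graw)
        y = Zs @ rng.normal(0, 0.5, 10) + rng.normal(0, 1, 30)
        post = BayesianRidge(y, Zs, transform=(means, sds)).fit(
            McmcConfig(1000, 500, 1, seed=0))
        fitted = post.mu_mean + Zs @ post.effect_means
        pred = predict_gebv(Graw[[3]], (means, sds), post)
        assert pred[0] == pytest.approx(fitted[3])

    def test_two_marker_hand_case(self):
        post = BayesianRidge(*_toy(0, n=10, m=2)).fit(
            McmcConfig(200, 100, 1, seed=0), sample_variances=False,
            sigma2_a=1.0, sigma2_e=1.0)
        post.effect_means[:] = [0.5, -1.0]
        means, sds = np.array([1.0, 1.0]), np.array([0.5, 1.0])
        G = np.array([[2.0, 0.0], [1.0, 1.0]])
        pred = predict_gebv(G, (means, sds), post)
        expect = post.mu_mean + np.array([
            (2 - 1) / 0.5 * 0.5 + (0 - 1) / 1.0 * -1.0,
            0.0,
        ])
        np.testing.assert_allclose(pred, expect)

    def test_marker_count_mismatch_rejected(self):
        post = BayesianRidge(*_toy(0)).fit(
            McmcConfig(200, 100, 1, seed=0), sample_variances=False,
            sigma2_a=1.0, sigma2_e=1.0)
        with pytest.raises(ValueError, match="marker count"):
            predict_gebv(np.zeros((2, 3)), (np.zeros(3), np.ones(3)), post)
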