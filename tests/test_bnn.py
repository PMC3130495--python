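"""Hierarchical BNN: parameter bookkeeping, Gamma hyperprior and conjugate
Gibbs algebra, HMC geometry, and small-scale posterior behavior."""

import numpy as np
import pytest
from scipy import integrate, stats

from ugtsel.bnn import (
    GroupPrior,
    MCMCSchedule,
    PosteriorSample,
    Topology,
    _forward,
    _leapfrog,
    _potential_and_grad,
    bnn_predict,
    default_groups,
    gamma_hyperprior_pdf,
    gibbs_update_precision,
    mcmc_train,
    param_count,
    sample_hyperprior,
)


class TestTopology:
    def test_param_count_closed_form(self):
        assert param_count(Topology(602, 301, 1)) == 181805
        assert param_count(Topology(1, 1, 1)) == 4

    def test_param_count_matches_structural_slices(self):
        for topo in (Topology(5, 3), Topology(10, 7), Topology(602, 301)):
            total = sum(s.stop - s.start for s in topo.slices().values())
            assert total == param_count(topo)
            # groups partition the flat vector
            stops = sorted(s.stop for s in topo.slices().values())
            assert stops[-1] == param_count(topo)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            Topology(0, 3)


class TestGammaHyperprior:
    def test_normalization(self):
        total, _ = integrate.quad(lambda t: gamma_hyperprior_pdf(t, 4.0, 2.0), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_sample_mean_approximates_scale_parameter(self):
        rng = np.random.default_rng(0)
        draws = sample_hyperprior(4.0, 2.0, rng, size=100_000)
        assert np.mean(draws) == pytest.approx(2.0, rel=0.02)

    def test_smaller_shape_spreads_distribution(self):
        """Closed-form variance 2 w^2 / alpha grows as alpha shrinks; sampled
        variances must agree."""
        rng = np.random.default_rng(1)
        for alpha, w in ((0.5, 2.0), (4.0, 2.0)):
            draws = sample_hyperprior(alpha, w, rng, size=200_000)
            assert np.var(draws) == pytest.approx(2 * w**2 / alpha, rel=0.05)
        assert 2 * 2.0**2 / 0.5 > 2 * 2.0**2 / 4.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gamma_hyperprior_pdf(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_hyperprior_pdf(-1.0, 1.0, 1.0)


class TestGibbsUpdate:
    def test_empty_group_returns_prior_draw(self):
        rng = np.random.default_rng(2)
        draws = np.array([gibbs_update_precision([], 4.0, 2.0, rng) for _ in range(5000)])
        _, p = stats.kstest(draws, stats.gamma(a=2.0, scale=1.0).cdf)
        assert p > 0.01

    def test_zero_weights_shift_shape_only(self):
        # k=2 zero weights: shape alpha/2 + 1, rate unchanged at alpha/2w
        rng = np.random.default_rng(3)
        alpha, w = 3.0, 1.5
        draws = np.array(
            [gibbs_update_precision([0.0, 0.0], alpha, w, rng) for _ in range(5000)]
        )
        expected = stats.gamma(a=alpha / 2 + 1, scale=2 * w / alpha)
        _, p = stats.kstest(draws, expected.cdf)
        assert p > 0.01

    def test_moments_match_conjugate_posterior(self):
        """Analytic conjugate algebra as oracle at 1e5 draws, rel. error < 2%."""
        rng = np.random.default_rng(4)
        weights = np.array([0.5, -1.2, 0.8, 2.0])
        alpha, w = 2.0, 1.0
        shape = alpha / 2 + len(weights) / 2
        rate = alpha / (2 * w) + 0.5 * np.sum(weights**2)
        draws = np.array(
            [gibbs_update_precision(weights, alpha, w, rng) for _ in range(100_000)]
        )
        assert np.mean(draws) == pytest.approx(shape / rate, rel=0.02)
        assert np.var(draws) == pytest.approx(shape / rate**2, rel=0.05)

    def test_exchangeable_in_weights(self):
        w = np.array([0.3, -0.7, 1.1])
        d1 = gibbs_update_precision(w, 2.0, 1.0, np.random.default_rng(9))
        d2 = gibbs_update_precision(w[::-1], 2.0, 1.0, np.random.default_rng(9))
        assert d1 == d2

    def test_scale_covariance(self):
        """Scaling weights by c multiplies the data term of the rate by c^2."""
        rng = np.random.default_rng(5)
        w = np.array([1.0, -1.0])
        c = 3.0
        alpha, wscale = 2.0, 1.0
        shape = alpha / 2 + 1.0
        rate_scaled = alpha / (2 * wscale) + 0.5 * c**2 * np.sum(w**2)
        draws = np.array(
            [gibbs_update_precision(c * w, alpha, wscale, rng) for _ in range(50_000)]
        )
        assert np.mean(draws) == pytest.approx(shape / rate_scaled, rel=0.03)


class TestHMCGeometry:
    def test_energy_drift_small_at_small_step(self):
        topo = Topology(2, 3)
        taus = np.ones(param_count(topo))
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 2))
        y = (x[:, 0] > 0).astype(float)
        grad_fn = lambda p: _potential_and_grad(p, topo, x, y, taus)
        params = rng.normal(size=param_count(topo)) * 0.3
        m0 = rng.standard_normal(params.size)
        u0, _ = grad_fn(params)
        h0 = u0 + 0.5 * m0 @ m0
        p1, m1, u1 = _leapfrog(params, m0, grad_fn, step=0.001, n_steps=50)
        h1 = u1 + 0.5 * m1 @ m1
        assert abs(h1 - h0) / max(abs(h0), 1.0) < 0.01

    def test_zero_step_trajectory_is_identity(self):
        topo = Topology(1, 1)
        taus = np.ones(param_count(topo))
        grad_fn = lambda p: _potential_and_grad(p, topo, np.zeros((0, 1)), np.zeros(0), taus)
        params = np.array([0.1, -0.2, 0.3, 0.0])
        m0 = np.array([1.0, -1.0, 0.5, 0.2])
        p1, m1, u1 = _leapfrog(params, m0, grad_fn, step=0.1, n_steps=0)
        assert np.array_equal(p1, params)
        assert np.array_equal(m1, m0)  # identity proposal: dH = 0, always accepted

    def test_gradient_matches_finite_differences(self):
        topo = Topology(2, 2)
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 2))
        y = np.array([0, 1, 1, 0, 1], dtype=float)
        taus = np.full(param_count(topo), 2.0)
        p0 = rng.normal(size=param_count(topo)) * 0.4
        u0, g = _potential_and_grad(p0, topo, x, y, taus)
        eps = 1e-6
        for i in range(p0.size):
            dp = p0.copy()
            dp[i] += eps
            u1, _ = _potential_and_grad(dp, topo, x, y, taus)
            assert (u1 - u0) / eps == pytest.approx(g[i], rel=1e-3, abs=1e-6)


class TestTraining:
    def test_zero_iteration_schedule_returns_initial_state(self):
        topo = Topology(2, 2)
        res = mcmc_train(
            np.zeros((0, 2)), np.zeros(0), topo,
            schedule=MCMCSchedule(phase1=0, phase2=0), rng=0,
        )
        assert len(res.samples) == 1
        assert np.array_equal(res.samples[0].weights, np.zeros(param_count(topo)))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            mcmc_train(np.ones((2, 1)), np.array([0.0, 2.0]), Topology(1, 1))

    def test_flat_likelihood_recovers_prior_marginals(self):
        """With no data and fixed precisions the long-run weight marginals are
        the prior Gaussians (two-sample KS against exact draws)."""
        topo = Topology(1, 2)
        groups = {name: GroupPrior(fixed=True, tau=1.0) for name in default_groups()}
        res = mcmc_train(
            np.zeros((0, 1)), np.zeros(0), topo, groups,
            MCMCSchedule(phase1=50, phase2=4000, leapfrog_steps=10, step_size=0.5, thin=4),
            rng=11,
        )
        draws = np.concatenate([s.weights for s in res.samples])
        exact = np.random.default_rng(12).standard_normal(draws.size)
        _, p = stats.ks_2samp(draws, exact)
        assert p > 0.01

    def test_separates_linearly_separable_classes(self):
        """Tiny 2-3-1 net on 20 separable points: posterior-mean prediction
        recovers the classes in nearly all seeded runs."""
        topo = Topology(2, 3)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.vstack([rng.normal(-1, 0.4, (10, 2)), rng.normal(1, 0.4, (10, 2))])
            y = np.r_[np.zeros(10), np.ones(10)]
            res = mcmc_train(
                x, y, topo, schedule=MCMCSchedule(phase1=50, phase2=200), rng=seed
            )
            _, labels = bnn_predict(res.samples, x, topo)
            wins += (labels == y).all()
        assert wins >= 9

    def test_divergent_trajectory_halves_step(self):
        topo = Topology(2, 3)
        rng = np.random.default_rng(13)
        x = rng.normal(size=(10, 2)) * 50
        y = (x[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="divergent"):
            res = mcmc_train(
                x, y, topo,
                schedule=MCMCSchedule(phase1=5, phase2=10, step_size=50.0, leapfrog_steps=30),
                rng=13,
            )
        assert res.diagnostics["final_step_size"] < 50.0


class TestPrediction:
    def test_identical_samples_equal_single_network(self):
        topo = Topology(2, 2)
        rng = np.random.default_rng(14)
        w = rng.normal(size=param_count(topo))
        x = rng.normal(size=(4, 2))
        samples = [PosteriorSample(weights=w, taus={}, iteration=i) for i in range(3)]
        probs, _ = bnn_predict(samples, x, topo)
        _, f = _forward(w, topo, x)
        assert np.allclose(probs, 1 / (1 + np.exp(-f)))

    def test_symmetric_samples_give_half_probability(self):
        """Mirroring the hidden-to-output weights and output bias flips the
        logit sign, so an f / -f posterior pair averages to probability 1/2."""
        topo = Topology(2, 2)
        rng = np.random.default_rng(15)
        w = rng.normal(size=param_count(topo))
        w_neg = w.copy()
        s = topo.slices()
        w_neg[s["hidden_output"]] *= -1
        w_neg[s["output_unit"]] *= -1
        x = rng.normal(size=(5, 2))
        probs, _ = bnn_predict(
            [PosteriorSample(w, {}, 0), PosteriorSample(w_neg, {}, 1)], x, topo
        )
        assert np.allclose(probs, 0.5)

    def test_two_term_average_by_hand(self):
        topo = Topology(1, 1)
        w1 = np.array([1.0, 0.0, 1.0, 0.0])
        w2 = np.array([0.5, 0.1, -0.3, 0.2])
        x = np.array([[0.7]])
        expected = np.mean(
            [1 / (1 + np.exp(-_forward(w, topo, x)[1])) for w in (w1, w2)], axis=0
        )
        probs, _ = bnn_predict(
            [PosteriorSample(w1, {}, 0), PosteriorSample(w2, {}, 1)], x, topo
        )
        assert np.allclose(probs, expected)

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bnn_predict([], np.zeros((1, 2)), Topology(2, 2))
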