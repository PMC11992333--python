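import numpy as np
import pytest
from scipy import stats

import rgmnet as rg
from rgmnet.sampler import (
    PriorHyperparameters,
    SamplerConfig,
    _FitContext,
    _invgamma_draw,
    _reflect,
    edge_probability_posterior,
    init_state,
    noise_variance_posterior,
    slab_variance_posterior,
    spike_slab_inclusion_probability,
    update_effect_entry_A,
    update_effect_entry_B,
    update_threshold,
)


def flat_summary(p=2, k=2):
    """n = 0 summary bundle: every likelihood term vanishes, so the chain
    samples from the prior."""
    return rg.SummaryStatistics(
        Syy=np.zeros((p, p)), Syx=np.zeros((p, k)), Sxx=np.eye(k), n=0
    )


class TestConjugateClosedForms:
    def test_inclusion_weight_hand_value(self):
        # rho=0.5, tau2=1, nu=0.01, a=0: spike density is 10x the slab,
        # so w = 1/11
        w = spike_slab_inclusion_probability(0.0, 1.0, 0.5, 0.01)
        assert w == pytest.approx(1 / 11, abs=1e-12)

    def test_inclusion_weight_limits(self):
        # large |a|: slab dominates
        assert spike_slab_inclusion_probability(50.0, 1.0, 0.5, 0.01) > 1 - 1e-9
        # nu -> 1: densities cancel, w -> rho
        assert spike_slab_inclusion_probability(1.3, 2.0, 0.37, 1 - 1e-12) == pytest.approx(0.37, abs=1e-6)

    def test_inclusion_weight_matches_density_ratio(self, rng):
        for _ in range(100):
            a = rng.normal(0, 2)
            tau2 = rng.uniform(0.1, 3)
            rho = rng.uniform(0.05, 0.95)
            nu = rng.uniform(1e-4, 0.5)
            slab = stats.norm.pdf(a, 0, np.sqrt(tau2))
            spike = stats.norm.pdf(a, 0, np.sqrt(nu * tau2))
            expected = rho * slab / (rho * slab + (1 - rho) * spike)
            assert spike_slab_inclusion_probability(a, tau2, rho, nu) == pytest.approx(
                expected, rel=1e-10
            )

    def test_slab_variance_posterior_hand_values(self):
        shape, rate = slab_variance_posterior(0.0, 1, 0.5, 0.5, 0.01)
        assert (float(shape), float(rate)) == (1.0, 0.5)
        shape, rate = slab_variance_posterior(1.0, 1, 0.5, 0.5, 0.01)
        assert (float(shape), float(rate)) == (1.0, 1.0)
        # spike scaling: gamma=0 divides the quadratic term by nu
        shape, rate = slab_variance_posterior(1.0, 0, 0.5, 0.5, 0.1)
        assert float(rate) == pytest.approx(0.5 + 1 / 0.2)

    def test_edge_probability_posterior_hand_values(self):
        assert edge_probability_posterior(4, 6, 1, 1) == (5, 3)
        assert edge_probability_posterior(0, 6, 1.5, 2.0) == (1.5, 8.0)

    def test_noise_variance_posterior(self):
        shape, rate = noise_variance_posterior(100, np.array([0.0]), 0.01, 0.02)
        assert shape == pytest.approx(50.01)
        assert rate[0] == pytest.approx(0.02)
        with pytest.raises(RuntimeError):
            noise_variance_posterior(10, np.array([-1e-6]), 0.01, 0.01)

    def test_conjugate_params_match_independent_oracle(self, rng):
        """100 random states: full-conditional parameters agree with an
        independently coded derivation."""
        for _ in range(100):
            a = rng.normal(0, 1)
            gamma = int(rng.integers(0, 2))
            a0, b0, nu = rng.uniform(0.1, 3, 3)
            nu = min(nu, 0.9)
            shape, rate = slab_variance_posterior(a, gamma, a0, b0, nu)
            c = 1.0 if gamma == 1 else nu
            assert float(shape) == pytest.approx(a0 + 0.5)
            assert float(rate) == pytest.approx(b0 + a * a / (2 * c))
            n_on = int(rng.integers(0, 13))
            ab = edge_probability_posterior(n_on, 12, a0, b0)
            assert ab == (a0 + n_on, b0 + 12 - n_on)

    def test_inverse_gamma_moments(self, rng):
        """Empirical moments of 1e5 inverse-gamma draws match the analytic
        mean within 3 Monte-Carlo standard errors."""
        shape, rate = 3.0, 2.0
        draws = _invgamma_draw(rng, np.full(100_000, shape), np.full(100_000, rate))
        mean = rate / (shape - 1)
        sd = np.sqrt(rate**2 / ((shape - 1) ** 2 * (shape - 2)))
        se = sd / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se
        assert (draws > 0).all()


class TestInitState:
    def test_initialization_rules(self, small_truth):
        S = rg.compute_summary_statistics(small_truth.data)
        cfg = SamplerConfig(seed=1)
        st = init_state(S, small_truth.D, cfg)
        assert np.all(st.A == 0) and np.all(st.B == 0)
        assert np.linalg.det(np.eye(st.A.shape[0]) - st.A) == 1.0
        assert np.array_equal(st.phi, small_truth.D.D)
        assert np.all(st.gamma == 0)
        np.testing.assert_allclose(st.sigma2, np.diag(S.Syy))
        h = cfg.hyper
        assert st.rho == h.aRho / (h.aRho + h.bRho)
        assert st.tA == h.tMaxA / 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(nIter=100, nBurnin=100)
        with pytest.raises(ValueError):
            SamplerConfig(Thin=0)
        with pytest.raises(ValueError):
            SamplerConfig(prior="lasso")

    def test_default_retention_count(self):
        assert SamplerConfig().n_retained == 8000
        assert SamplerConfig(nIter=1000, nBurnin=100, Thin=7).n_retained == 128


class TestMetropolisUpdates:
    def _ctx(self, p=3, n=500, seed=0):
        truth = rg.simulate(rg.SimulationDesign(p=p, n=n, seed=seed))
        S = rg.compute_summary_statistics(truth.data)
        cfg = SamplerConfig(seed=seed)
        state = init_state(S, truth.D, cfg)
        return state, _FitContext(S, truth.D, state), cfg.hyper

    def test_effect_updates_keep_state_consistent(self, rng):
        state, ctx, hyper = self._ctx()
        for _ in range(200):
            i, j = rng.integers(0, 3, 2)
            if i != j:
                update_effect_entry_A(state, ctx, int(i), int(j), hyper, rng)
        # workspace and cached residuals agree with direct recomputation
        M = np.eye(3) - state.A
        assert ctx.ws.logabsdet == pytest.approx(np.linalg.slogdet(M)[1], abs=1e-8)
        np.testing.assert_allclose(ctx.Rdiag, ctx.rdiag(), atol=1e-8)

    def test_B_update_requires_support(self, rng):
        state, ctx, hyper = self._ctx()
        with pytest.raises(ValueError, match="support"):
            update_effect_entry_B(state, ctx, 0, 1, hyper, rng)  # D = identity

    def test_off_support_B_stays_zero(self, small_truth, small_fit):
        off = small_truth.D.D == 0
        assert np.all(small_fit.BEst[off] == 0)
        assert np.all(small_fit.PhiEst[off] == 0)

    def test_reflection_maps_into_support(self):
        assert _reflect(-0.2, 1.0) == pytest.approx(0.2)
        assert _reflect(1.3, 1.0) == pytest.approx(0.7)
        assert _reflect(2.6, 1.0) == pytest.approx(0.6)
        assert _reflect(0.4, 1.0) == pytest.approx(0.4)

    def test_threshold_update_keeps_indicator_identity(self, rng):
        """After a threshold move, gamma equals 1(|A0| > tA) elementwise
        (flat likelihood: every proposal is accepted)."""
        p = 3
        S = flat_summary(p, p)
        D = rg.InstrumentAssignment(np.eye(p, dtype=int))
        cfg = SamplerConfig(prior="Threshold", seed=0)
        state = init_state(S, D, cfg)
        state.A0 = rng.normal(0, 0.5, (p, p))
        np.fill_diagonal(state.A0, 0.0)
        ctx = _FitContext(S, D, state)
        accepted = update_threshold(state, ctx, "A", cfg.hyper, rng)
        assert accepted
        expected = (np.abs(state.A0) > state.tA).astype(int)
        np.fill_diagonal(expected, 0)
        assert np.array_equal(state.gamma, expected)
        np.testing.assert_allclose(state.A, state.A0 * expected, atol=0)


class TestRunMcmc:
    def test_bit_reproducibility(self, small_truth):
        cfg = SamplerConfig(nIter=300, nBurnin=100, seed=42)
        r1 = rg.run_mcmc(small_truth.data, small_truth.D, cfg)
        r2 = rg.run_mcmc(small_truth.data, small_truth.D, cfg)
        assert np.array_equal(r1.AEst, r2.AEst)
        assert np.array_equal(r1.GammaPst, r2.GammaPst)
        assert np.array_equal(r1.LLPst, r2.LLPst)
        assert r1.RhoEst == r2.RhoEst

    def test_different_seeds_differ(self, small_truth):
        r1 = rg.run_mcmc(small_truth.data, small_truth.D,
                         SamplerConfig(nIter=300, nBurnin=100, seed=1))
        r2 = rg.run_mcmc(small_truth.data, small_truth.D,
                         SamplerConfig(nIter=300, nBurnin=100, seed=2))
        assert not np.array_equal(r1.AEst, r2.AEst)

    def test_retention_bookkeeping(self, small_fit):
        assert small_fit.LLPst.shape[0] == small_fit.GammaPst.shape[0] == 800
        assert 0 < small_fit.AccptA < 1
        assert 0 < small_fit.AccptB < 1
        np.testing.assert_allclose(
            small_fit.GammaEst, small_fit.GammaPst.mean(axis=0), atol=1e-12
        )

    def test_spike_slab_sets_latent_means_to_effect_means(self, small_fit):
        assert np.array_equal(small_fit.A0Est, small_fit.AEst)
        assert np.isnan(small_fit.tAEst)

    def test_threshold_prior_runs_and_reports(self, small_truth):
        cfg = SamplerConfig(nIter=400, nBurnin=100, seed=3, prior="Threshold")
        res = rg.run_mcmc(small_truth.data, small_truth.D, cfg)
        assert 0 < res.tAEst < cfg.hyper.tMaxA
        assert 0 <= res.AccpttA <= 1
        assert res.GammaPst.shape == (300, 5, 5)

    def test_regression_summary_path_runs(self, small_truth):
        bundles = rg.bundle_input_formats(small_truth.data, small_truth.D)
        cfg = SamplerConfig(nIter=300, nBurnin=100, seed=7)
        res = rg.run_mcmc(bundles["regression_summary"], small_truth.D, cfg)
        assert np.isfinite(res.LLPst).all()

    def test_graph_edges_match_adjacency(self, small_fit):
        assert len(small_fit.Graph) == int(small_fit.zAEst.sum())
        for src, tgt, eff, prob in small_fit.Graph:
            assert small_fit.zAEst[tgt, src] == 1
            assert eff == small_fit.AEst[tgt, src]
            assert prob > 0.5

    def test_noise_posterior_concentrates_at_truth(self, rng):
        """With (A, B) fixed at the truth and n = 1e4, the sigma2 full
        conditional concentrates near the generating variance."""
        truth = rg.simulate(rg.SimulationDesign(p=2, n=10_000, seed=4,
                                                variance_explained=0.5))
        S = rg.compute_summary_statistics(truth.data)
        R = np.diag(
            (np.eye(2) - truth.A_true) @ S.Syy @ (np.eye(2) - truth.A_true).T
            - 2 * (np.eye(2) - truth.A_true) @ S.Syx @ truth.B_true.T
            + truth.B_true @ S.Sxx @ truth.B_true.T
        )
        shape, rate = noise_variance_posterior(S.n, R, 0.01, 0.01)
        draws = _invgamma_draw(rng, np.full(2000, shape), np.tile(rate[0], 2000))
        assert abs(draws.mean() - truth.Sigma_true[0]) / truth.Sigma_true[0] < 0.1
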