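import numpy as np
import pytest

from conftest import build_context, random_sample

from crpen import (
    BaselineHazard,
    CompetingRisksSample,
    LinkFunction,
    compute_weights,
    fit_censoring_survival,
    update_baseline,
    weighted_loglik,
)
from crpen.likelihood import LikelihoodContext, eta_at_events


class TestBaselineSelfConsistency:
    def test_nelson_aalen_increments_no_censoring_no_competing(self, no_censoring_sample):
        """At beta = 0 the jumps are the reciprocal at-risk counts."""
        ctx = build_context(no_censoring_sample)
        jumps = ctx.solve_baseline(np.zeros(1), np.full(4, 0.25))
        np.testing.assert_allclose(jumps, [1 / 4, 1 / 3, 1 / 2, 1.0])

    def test_jumps_equal_reciprocal_pseudo_risk_with_competing(self):
        """Five subjects, one competing event, no censoring, beta = 0."""
        s = CompetingRisksSample(
            times=np.array([1.0, 1.5, 2.0, 3.0, 4.0]),
            delta=np.ones(5, dtype=int),
            cause=np.array([1, 2, 1, 1, 1]),
            covariates=np.zeros((5, 1)),
        )
        ctx = build_context(s)
        jumps = ctx.solve_baseline(np.zeros(1), np.full(4, 0.2))
        # pseudo-risk sizes at 1.0, 2.0, 3.0, 4.0: 5, 4 (competing stays), 3, 2
        np.testing.assert_allclose(jumps, [1 / 5, 1 / 4, 1 / 3, 1 / 2])

    def test_breslow_increments_any_beta(self, tiny_sample):
        """Identity link: converged jumps match the weighted Breslow formula."""
        ctx = build_context(tiny_sample)
        beta = np.array([0.4, -0.7])
        jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / 6))
        # independent computation of sum_i w_i(t) Y_i(t) exp(b'Z_i)
        s = tiny_sample
        ghat = fit_censoring_survival(s)
        wm = compute_weights(s, ghat)
        eta = np.exp(s.covariates @ beta)
        expected = []
        for j, t in enumerate(wm.eval_times):
            denom = 0.0
            for i in range(s.n):
                if s.times[i] >= t:
                    denom += eta[i]
                elif s.delta[i] == 1 and s.cause[i] >= 2:
                    denom += wm.weights[i, j] * eta[i]
            expected.append(1.0 / denom)
        np.testing.assert_allclose(jumps, expected, rtol=1e-10)

    def test_fixed_point_is_stable(self, sim_sample):
        ctx = build_context(sim_sample, LinkFunction.prop_odds())
        beta = np.full(5, 0.2)
        jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / ctx.n))
        again = ctx.baseline_update_step(beta, jumps)
        assert np.max(np.abs(again - jumps)) < 1e-8

    def test_update_baseline_wrapper(self, tiny_sample):
        ctx = build_context(tiny_sample)
        base = BaselineHazard.initial(tiny_sample.cause1_event_times(), tiny_sample.n)
        ghat = fit_censoring_survival(tiny_sample)
        wm = compute_weights(tiny_sample, ghat)
        out = update_baseline(np.zeros(2), base, tiny_sample,
                              wm, LinkFunction.fine_gray())
        assert np.all(out.jumps > 0)
        assert np.all(np.diff(out.cumulative) > 0)


class TestWeightedLoglik:
    def test_single_event_poisson_kernel(self):
        """One cause-1 event with jump a contributes log(a) - a at beta = 0."""
        s = CompetingRisksSample(
            times=np.array([2.0]), delta=np.array([1]), cause=np.array([1]),
            covariates=np.zeros((1, 1)),
        )
        ctx = build_context(s)
        for a in (0.3, 1.0, 2.5):
            assert ctx.loglik(np.zeros(1), np.array([a])) == pytest.approx(np.log(a) - a)

    def test_factorizes_into_partial_likelihood(self, tiny_sample):
        """Identity-link profile log-likelihood differences equal weighted
        Fine-Gray partial-likelihood differences (the two-factor form)."""
        ctx = build_context(tiny_sample)
        s = tiny_sample
        ghat = fit_censoring_survival(s)
        wm = compute_weights(s, ghat)

        def partial_loglik(beta):
            ev = sorted(np.flatnonzero(s.cause == 1), key=lambda i: s.times[i])
            ll = 0.0
            for e, i in enumerate(ev):
                t = s.times[i]
                j = np.searchsorted(wm.eval_times, t)
                denom = 0.0
                for q in range(s.n):
                    if s.times[q] >= t:
                        denom += np.exp(s.covariates[q] @ beta)
                    elif s.delta[q] == 1 and s.cause[q] >= 2:
                        denom += wm.weights[q, j] * np.exp(s.covariates[q] @ beta)
                ll += s.covariates[i] @ beta - np.log(denom)
            return ll

        def profile(beta):
            jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / ctx.n))
            return ctx.loglik(beta, jumps)

        b1, b2 = np.array([0.5, -0.3]), np.array([-0.2, 0.9])
        assert profile(b1) - profile(b2) == pytest.approx(
            partial_loglik(b1) - partial_loglik(b2), abs=1e-9
        )

    def test_log_link_limit_matches_identity(self, tiny_sample):
        beta = np.array([0.3, -0.4])
        ctx_id = build_context(tiny_sample, LinkFunction.fine_gray())
        ctx_r = build_context(tiny_sample, LinkFunction("logarithmic", 1e-9))
        jumps = ctx_id.solve_baseline(beta, np.full(ctx_id.m, 1 / 6))
        assert ctx_r.loglik(beta, jumps) == pytest.approx(
            ctx_id.loglik(beta, jumps), abs=1e-8
        )

    def test_nonpositive_jump_rejected(self, tiny_sample):
        ctx = build_context(tiny_sample)
        with pytest.raises(ValueError, match="positive"):
            ctx.loglik(np.zeros(2), np.array([0.1, 0.0, -0.1]))


class TestGradient:
    @pytest.mark.parametrize("link", [LinkFunction.fine_gray(), LinkFunction.prop_odds()])
    def test_matches_central_differences(self, link):
        """Analytic score equals finite differences on 20 random fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            s = random_sample(rng, n=35, d=3)
            ctx = build_context(s, link)
            beta = rng.normal(0, 0.4, 3)
            jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / ctx.n))
            g = ctx.gradient(beta, jumps)
            fd = np.zeros(3)
            for j in range(3):
                e = np.zeros(3)
                e[j] = 1e-6
                fd[j] = (ctx.loglik(beta + e, jumps) - ctx.loglik(beta - e, jumps)) / 2e-6
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_score_antisymmetric_under_sign_flip(self):
        """Negating every covariate negates the score at beta = 0."""
        rng = np.random.default_rng(17)
        s = random_sample(rng, n=30, d=2)
        from dataclasses import replace

        flipped = replace(s, covariates=-s.covariates)
        ctx, ctx_f = build_context(s), build_context(flipped)
        jumps = ctx.solve_baseline(np.zeros(2), np.full(ctx.m, 1 / ctx.n))
        g = ctx.gradient(np.zeros(2), jumps)
        g_f = ctx_f.gradient(np.zeros(2), jumps)
        np.testing.assert_allclose(g_f, -g, atol=1e-10)

    @pytest.mark.parametrize("link", [LinkFunction.fine_gray(), LinkFunction.prop_odds()])
    def test_directional_curvature_matches_differences(self, link, sim_sample):
        ctx = build_context(sim_sample, link)
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.3, 5)
        direction = rng.normal(size=5)
        jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / ctx.n))
        _, f2 = ctx.score_and_curv(beta, jumps)
        analytic = f2 @ (ctx.Z @ direction) ** 2
        h = 1e-5
        fd = ((ctx.gradient(beta + h * direction, jumps)
               - ctx.gradient(beta - h * direction, jumps)) / (2 * h)) @ direction
        assert analytic == pytest.approx(fd, rel=1e-5)


class TestEtaAtEvents:
    def test_zero_beta_gives_ones(self, tiny_sample):
        out = eta_at_events(np.zeros(2), tiny_sample)
        assert out.shape == (6, tiny_sample.n_cause1)
        assert np.all(out == 1.0)

    def test_direct_evaluation(self, tiny_sample):
        out = eta_at_events(np.array([np.log(2.0), 0.0]), tiny_sample)
        np.testing.assert_allclose(out[:, 0], 2.0 ** tiny_sample.covariates[:, 0])

    def test_overflow_clipped(self, tiny_sample, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="crpen.likelihood"):
            out = eta_at_events(np.array([2000.0, 0.0]), tiny_sample)
        assert np.all(np.isfinite(out))
        assert any("clipped" in r.message for r in caplog.records)


def test_public_wrappers_consistent(tiny_sample):
    ghat = fit_censoring_survival(tiny_sample)
    wm = compute_weights(tiny_sample, ghat)
    link = LinkFunction.fine_gray()
    ctx = LikelihoodContext(tiny_sample, wm, link)
    beta = np.array([0.1, 0.2])
    jumps = ctx.solve_baseline(beta, np.full(ctx.m, 1 / 6))
    base = BaselineHazard(event_times=wm.eval_times, jumps=jumps)
    assert weighted_loglik(beta, base, tiny_sample, wm, link) == pytest.approx(
        ctx.loglik(beta, jumps)
    )
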