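import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import build_context

from crpen import LinkFunction, PenaltySpec, fit_at_lambda
from crpen.optimizer import (
    OptimizerState,
    _edge_time,
    _FixedBaselineProblem,
    directional_gradient,
    kkt_residuals,
    step,
)
from crpen.simulate import make_design, simulate_dataset
from crpen.tuning import lambda_max


class QuadraticContext:
    """1-d quadratic stand-in for the likelihood: l(b) = -(b - target)^2 / 2."""

    def __init__(self, target):
        self.target = target
        self.Z = np.array([[1.0]])
        self.d = 1
        self.n = 1

    def loglik(self, beta, jumps):
        return -0.5 * float((beta[0] - self.target) ** 2)

    def gradient(self, beta, jumps):
        return np.array([self.target - beta[0]])

    def score_and_curv(self, beta, jumps):
        return np.array([self.target - beta[0]]), np.array([-1.0])


class TestDirectionalGradient:
    def test_active_coordinate_penalized_gradient(self):
        spec = PenaltySpec("alasso", 0.5, adaptive_weights=np.array([1.0]))
        kappa = directional_gradient(np.array([0.3]), np.array([2.0]), spec)
        assert kappa[0] == pytest.approx(2.0 - 0.5)

    def test_zero_inside_subgradient_interval(self):
        spec = PenaltySpec("alasso", 0.5, adaptive_weights=np.array([1.0]))
        kappa = directional_gradient(np.array([0.0]), np.array([0.3]), spec)
        assert kappa[0] == 0.0

    def test_shrinkage_rule_at_zero(self):
        spec = PenaltySpec("alasso", 0.5, adaptive_weights=np.array([1.0]))
        kappa = directional_gradient(np.array([0.0]), np.array([2.0]), spec)
        assert kappa[0] == pytest.approx(1.5)

    def test_scale_multiplies_threshold(self):
        spec = PenaltySpec("mcp", 0.5)
        kappa = directional_gradient(np.array([0.0]), np.array([2.0]), spec, scale=3.0)
        assert kappa[0] == pytest.approx(0.5)


def test_edge_time_example():
    assert _edge_time(np.array([0.5]), np.array([-1.0])) == pytest.approx(0.5)
    assert _edge_time(np.array([0.5]), np.array([1.0])) == np.inf


class TestStepSoftThreshold:
    @pytest.mark.parametrize("target, lam", [(2.0, 0.5), (-1.5, 0.7), (0.3, 0.5)])
    def test_converges_to_soft_threshold(self, target, lam):
        """On a quadratic surrogate with a lasso penalty the iteration
        reaches the closed-form soft-threshold solution."""
        ctx = QuadraticContext(target)
        spec = PenaltySpec("alasso", lam, adaptive_weights=np.array([1.0]))
        problem = _FixedBaselineProblem(ctx, np.array([1.0]), spec, scale=1.0)
        beta = np.zeros(1)
        state = OptimizerState(
            beta=beta,
            kappa=directional_gradient(beta, ctx.gradient(beta, None), spec),
            t_edge=np.inf, t_opt=np.inf, objective=problem.objective(beta),
        )
        for _ in range(60):
            if np.max(np.abs(state.kappa)) < 1e-10:
                break
            state = step(state, problem)
        expected = np.sign(target) * max(abs(target) - lam, 0.0)
        assert state.beta[0] == pytest.approx(expected, abs=1e-8)

    def test_objective_never_decreases(self):
        ctx = QuadraticContext(3.0)
        spec = PenaltySpec("mcp", 0.4)
        problem = _FixedBaselineProblem(ctx, np.array([1.0]), spec, scale=1.0)
        beta = np.zeros(1)
        state = OptimizerState(
            beta=beta,
            kappa=directional_gradient(beta, ctx.gradient(beta, None), spec),
            t_edge=np.inf, t_opt=np.inf, objective=problem.objective(beta),
        )
        objs = [state.objective]
        for _ in range(30):
            if np.max(np.abs(state.kappa)) < 1e-10:
                break
            state = step(state, problem)
            objs.append(state.objective)
        assert np.all(np.diff(objs) >= -1e-12)


def naive_finegray_estimate(sample, ghat, d):
    """Independent weighted partial-likelihood maximizer (explicit loops)."""
    X, delta, cause, Z = sample.times, sample.delta, sample.cause, sample.covariates
    ev = sorted(np.flatnonzero(cause == 1), key=lambda i: X[i])

    def negloglik(beta):
        ll = 0.0
        for i in ev:
            t = X[i]
            denom = 0.0
            for j in range(sample.n):
                if X[j] >= t:
                    w = 1.0
                elif delta[j] == 1 and cause[j] >= 2:
                    w = float(ghat.at_left(t)) / max(float(ghat.at_left(X[j])), 1e-10)
                else:
                    continue
                denom += w * np.exp(Z[j] @ beta)
            ll += Z[i] @ beta - np.log(denom)
        return -ll

    return minimize(negloglik, np.zeros(d), method="BFGS").x


class TestFitAtLambda:
    def test_huge_lambda_gives_null_model(self, sim_sample):
        ctx = build_context(sim_sample)
        st = fit_at_lambda(ctx, None, None, PenaltySpec("mcp", 1e9))
        assert st.support.size == 0
        null_jumps = ctx.solve_baseline(np.zeros(5), np.full(ctx.m, 1 / ctx.n))
        np.testing.assert_allclose(st.baseline.jumps, null_jumps)

    def test_unpenalized_matches_finegray_oracle(self):
        from crpen import fit_censoring_survival, compute_weights

        design = make_design("table1", n=80, d=5, k=0.5, seed=13)
        s = simulate_dataset(design).sample
        ghat = fit_censoring_survival(s)
        wm = compute_weights(s, ghat)
        st = fit_at_lambda(s, wm, LinkFunction.fine_gray(), PenaltySpec("mcp", 0.0))
        oracle = naive_finegray_estimate(s, ghat, 5)
        np.testing.assert_allclose(st.beta, oracle, atol=1e-3)

    def test_kkt_at_convergence_convex_penalty(self, sim_sample):
        ctx = build_context(sim_sample)
        spec = PenaltySpec("alasso", 0.05, adaptive_weights=np.ones(5))
        st = fit_at_lambda(ctx, None, None, spec)
        act, inact = kkt_residuals(st, ctx, spec)
        assert act.size == 0 or np.max(act) < 1e-4 * ctx.n
        assert inact.size == 0 or np.max(inact) < 1e-4 * ctx.n

    def test_warm_vs_cold_start_agree(self):
        design = make_design("table1", n=150, d=5, k=0.5, seed=7)
        ctx = build_context(simulate_dataset(design).sample)
        spec = PenaltySpec("alasso", adaptive_weights=np.ones(5))
        lmax = lambda_max(ctx, spec=spec)
        lam_hi, lam_lo = 0.6 * lmax, 0.45 * lmax
        warm_src = fit_at_lambda(ctx, None, None, spec.with_lambda(lam_hi))
        warm = fit_at_lambda(ctx, None, None, spec.with_lambda(lam_lo),
                             beta_init=warm_src.beta, baseline_init=warm_src.baseline)
        cold = fit_at_lambda(ctx, None, None, spec.with_lambda(lam_lo))
        np.testing.assert_array_equal(warm.support, cold.support)
        np.testing.assert_allclose(warm.beta, cold.beta, atol=1e-5)

    def test_nonconvex_multistart_strong_signal_agrees(self):
        """MCP fits from several starts land on the same support when the
        signal is strong."""
        design = make_design("table1", n=200, d=5, k=0.8, seed=3)
        ctx = build_context(simulate_dataset(design).sample)
        spec = PenaltySpec("mcp", 0.08)
        rng = np.random.default_rng(0)
        supports = set()
        best = -np.inf
        for _ in range(5):
            b0 = rng.normal(0, 0.1, 5)
            st = fit_at_lambda(ctx, None, None, spec, beta_init=b0)
            supports.add(tuple(st.support.tolist()))
        assert len(supports) == 1
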