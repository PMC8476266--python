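"""Weighted nonparametric likelihood for subdistribution hazards.

The cumulative baseline ``A0`` is treated as a step function with one
jump per ordered cause-1 event time; the jump sizes are profiled out by
a self-consistency (fixed-point) update at fixed regression
coefficients.  The discretized weighted log-likelihood is

    l(b, a) = sum_{i: eps=1} [ log a_{j(i)} + b'Z_i + log g'(u_i) ]
            - sum_i g(u_i)
            - sum_{i: eps>=2} sum_{t_k > X_i} w_i(t_k) e^{b'Z_i} a_k g'(v_ik)

with ``u_i = e^{b'Z_i} A(X_i)`` and ``v_ik = e^{b'Z_i} A(t_k)``.  The
first two blocks cover every subject up to its own observed time; the
third keeps competing-event subjects in the pseudo-risk set after their
event, discounted by the IPCW weights.  For the identity link this
reduces to the weighted Breslow/Fine-Gray form: jump updates become
``1 / sum_i w_i(t_j) Y_i(t_j) e^{b'Z_i}`` and the profile likelihood is
the weighted Fine-Gray partial likelihood up to an additive constant.

With time-fixed covariates every subject's contribution is a scalar
function of its linear predictor, so the gradient and Hessian of the
likelihood take the forms ``Z' f`` and ``Z' diag(f2) Z`` with
per-subject scalars computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import CompetingRisksSample, LinkFunction
from .ipcw import WeightMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineHazard",
    "ModelState",
    "LikelihoodContext",
    "eta_at_events",
    "update_baseline",
    "weighted_loglik",
    "loglik_gradient",
    "DegeneratePseudoRiskError",
]

LINPRED_CLIP = 500.0
BASELINE_TOL = 1e-8
BASELINE_MAX_ITER = 500


class DegeneratePseudoRiskError(RuntimeError):
    """Raised when a baseline self-consistency denominator is nonpositive."""


@dataclass(frozen=True)
class BaselineHazard:
    """Step-function cumulative subdistribution baseline hazard."""

    event_times: np.ndarray  # ordered distinct cause-1 event times
    jumps: np.ndarray  # positive jump sizes

    def __post_init__(self):
        object.__setattr__(self, "event_times", np.asarray(self.event_times, dtype=float))
        object.__setattr__(self, "jumps", np.asarray(self.jumps, dtype=float))

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.jumps)

    def cum_at(self, t) -> np.ndarray:
        """Right-continuous cumulative baseline ``A0(t)`` (jump at t included)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([0.0], self.cumulative))
        return vals[idx]

    @staticmethod
    def initial(event_times: np.ndarray, n: int) -> "BaselineHazard":
        """Flat start: equal jumps 1/n at each cause-1 event time."""
        m = len(event_times)
        return BaselineHazard(event_times=event_times, jumps=np.full(m, 1.0 / n))


@dataclass(frozen=True)
class ModelState:
    beta: np.ndarray
    baseline: BaselineHazard
    link: LinkFunction
    loglik: float
    gradient: np.ndarray
    converged: bool = True
    n_iter: int = 0

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0.0)


def _clip_linpred(theta: np.ndarray) -> np.ndarray:
    if np.any(np.abs(theta) > LINPRED_CLIP):
        logger.warning("linear predictor clipped to +/-%g to avoid overflow", LINPRED_CLIP)
        theta = np.clip(theta, -LINPRED_CLIP, LINPRED_CLIP)
    return theta


def _rev_cumsum(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(x, axis=axis), axis=axis), axis=axis)


class LikelihoodContext:
    """Precomputed index structures for repeated likelihood evaluations.

    Built once per (sample, weights, link); all heavy per-iteration work
    is vectorised against these arrays.
    """

    def __init__(self, sample: CompetingRisksSample, weights: WeightMatrix, link: LinkFunction):
        self.sample = sample
        self.link = link
        self.grid = np.asarray(weights.eval_times, dtype=float)
        self.m = len(self.grid)
        if self.m == 0:
            raise ValueError("no cause-1 event times")
        X = sample.times
        self.Z = sample.covariates
        self.n, self.d = self.Z.shape
        # number of grid times <= X_i  (A(X_i) = cumA[own_idx - 1])
        self.own_idx = np.searchsorted(self.grid, X, side="right")
        # cause-1 subjects ordered by event time: grid[e] == X[subj_of_event[e]]
        c1 = np.flatnonzero(sample.cause == 1)
        self.subj_of_event = c1[np.argsort(X[c1], kind="stable")]
        self.is_c1 = sample.cause == 1
        # competing-cause subjects (all causes >= 2 pooled)
        self.i2 = np.flatnonzero((sample.delta == 1) & (sample.cause >= 2))
        if self.i2.size:
            post = self.grid[None, :] > X[self.i2, None]
            self.W2 = weights.weights[self.i2] * post  # (n2, m), post-event only
        else:
            self.W2 = np.zeros((0, self.m))
        # at-risk suffix structures
        self.order = np.argsort(X, kind="stable")
        self.X_sorted = X[self.order]
        self.grid_pos = np.searchsorted(self.X_sorted, self.grid, side="left")
        self.Z1sum = self.Z[self.subj_of_event].sum(axis=0)

    def restrict(self, cols: np.ndarray) -> "LikelihoodContext":
        """Shallow view of the context with the covariate matrix sliced.

        The event grid, weights and risk structures are covariate-free,
        so refits on a support need no recomputation.
        """
        import copy

        sub = copy.copy(self)
        sub.Z = self.Z[:, np.atleast_1d(cols)]
        sub.d = sub.Z.shape[1]
        sub.Z1sum = sub.Z[self.subj_of_event].sum(axis=0)
        return sub

    # -- elementary pieces --------------------------------------------------
    def linpred(self, beta: np.ndarray) -> np.ndarray:
        return _clip_linpred(self.Z @ beta)

    def _u_v(self, eta: np.ndarray, jumps: np.ndarray):
        cumA = np.cumsum(jumps)
        A_own = np.concatenate(([0.0], cumA))[self.own_idx]
        u = eta * A_own
        V2 = eta[self.i2, None] * cumA[None, :] if self.i2.size else None
        return u, V2, cumA

    def _suffix_at_grid(self, per_subject: np.ndarray) -> np.ndarray:
        """``out[j] = sum_{i: X_i >= grid[j]} per_subject[i]``."""
        s = np.concatenate((_rev_cumsum(per_subject[self.order]), [0.0]))
        return s[self.grid_pos]

    # -- likelihood, score, curvature ---------------------------------------
    def loglik(self, beta: np.ndarray, jumps: np.ndarray) -> float:
        if np.any(jumps <= 0):
            raise ValueError("baseline jumps must be positive")
        link = self.link
        theta = self.linpred(beta)
        eta = np.exp(theta)
        u, V2, _ = self._u_v(eta, jumps)
        ev = self.subj_of_event
        t1 = float(np.sum(np.log(jumps) + theta[ev] + np.log(link.dg(u[ev]))))
        t2 = float(np.sum(link.g(u)))
        t3 = 0.0
        if self.i2.size:
            t3 = float(np.sum(self.W2 * jumps[None, :] * eta[self.i2, None] * link.dg(V2)))
        return t1 - t2 - t3

    def _per_subject_score(self, eta: np.ndarray, u: np.ndarray, V2, jumps: np.ndarray) -> np.ndarray:
        link = self.link
        dg = link.dg(u)
        f = -(dg * u)
        if not link.is_identity:
            psi = link.d2g(u[self.is_c1]) / link.dg(u[self.is_c1])
            f[self.is_c1] += 1.0 + u[self.is_c1] * psi
        else:
            f[self.is_c1] += 1.0
        if self.i2.size:
            dgv = link.dg(V2)
            if link.is_identity:
                inner = dgv
            else:
                inner = dgv + V2 * link.d2g(V2)
            f[self.i2] -= np.sum(self.W2 * jumps[None, :] * inner, axis=1) * eta[self.i2]
        return f

    def _per_subject_curv(self, eta: np.ndarray, u: np.ndarray, V2, jumps: np.ndarray) -> np.ndarray:
        link = self.link
        f2 = -(link.d2g(u) * u**2 + link.dg(u) * u)
        if not link.is_identity:
            uc = u[self.is_c1]
            dgc, d2gc, d3gc = link.dg(uc), link.d2g(uc), link.d3g(uc)
            psi = d2gc / dgc
            dpsi = (d3gc * dgc - d2gc**2) / dgc**2
            f2[self.is_c1] += (dpsi * uc + psi) * uc
        if self.i2.size:
            if link.is_identity:
                inner = link.dg(V2)
            else:
                inner = link.dg(V2) + 3.0 * V2 * link.d2g(V2) + V2**2 * link.d3g(V2)
            f2[self.i2] -= np.sum(self.W2 * jumps[None, :] * inner, axis=1) * eta[self.i2]
        return f2

    def gradient(self, beta: np.ndarray, jumps: np.ndarray) -> np.ndarray:
        eta = np.exp(self.linpred(beta))
        u, V2, _ = self._u_v(eta, jumps)
        f = self._per_subject_score(eta, u, V2, jumps)
        return self.Z.T @ f

    def score_and_curv(self, beta: np.ndarray, jumps: np.ndarray):
        """Per-subject score/curvature scalars ``(f, f2)`` of the loglik."""
        eta = np.exp(self.linpred(beta))
        u, V2, _ = self._u_v(eta, jumps)
        f = self._per_subject_score(eta, u, V2, jumps)
        f2 = self._per_subject_curv(eta, u, V2, jumps)
        return f, f2

    # -- baseline self-consistency ------------------------------------------
    def baseline_denominator(self, beta: np.ndarray, jumps: np.ndarray) -> np.ndarray:
        """``n * Phi_n(t_j)`` -- the stationarity denominator per event time."""
        link = self.link
        eta = np.exp(self.linpred(beta))
        u, V2, _ = self._u_v(eta, jumps)
        term1 = self._suffix_at_grid(eta * link.dg(u))
        phi = term1
        if not link.is_identity:
            ev = self.subj_of_event
            q = eta[ev] * link.d2g(u[ev]) / link.dg(u[ev])
            phi = phi - _rev_cumsum(q)
        if self.i2.size:
            dgv = link.dg(V2)
            phi = phi + (self.W2 * dgv).T @ eta[self.i2]
            if not link.is_identity:
                M = (self.W2 * jumps[None, :] * link.d2g(V2)) * (eta[self.i2] ** 2)[:, None]
                phi = phi + _rev_cumsum(M.sum(axis=0))
        return phi

    def baseline_update_step(self, beta: np.ndarray, jumps: np.ndarray) -> np.ndarray:
        phi = self.baseline_denominator(beta, jumps)
        if np.any(phi <= 0):
            raise DegeneratePseudoRiskError(
                "degenerate pseudo-risk set: nonpositive baseline denominator"
            )
        return 1.0 / phi

    def solve_baseline(
        self,
        beta: np.ndarray,
        jumps: np.ndarray,
        tol: float = BASELINE_TOL,
        max_iter: int = BASELINE_MAX_ITER,
    ) -> np.ndarray:
        """Iterate the jump self-consistency map to its fixed point."""
        a = np.asarray(jumps, dtype=float)
        for _ in range(max_iter):
            a_new = self.baseline_update_step(beta, a)
            delta = float(np.max(np.abs(a_new - a)))
            a = a_new
            if delta < tol:
                break
        return a


# ---------------------------------------------------------------------------
# spec-level functional wrappers


def eta_at_events(beta: np.ndarray, sample: CompetingRisksSample) -> np.ndarray:
    """``exp(b'Z_i)`` replicated over the cause-1 event grid (n x m)."""
    theta = _clip_linpred(sample.covariates @ np.asarray(beta, dtype=float))
    m = sample.n_cause1
    return np.repeat(np.exp(theta)[:, None], m, axis=1)


def update_baseline(
    beta: np.ndarray,
    baseline: BaselineHazard,
    sample: CompetingRisksSample,
    weights: WeightMatrix,
    link: LinkFunction,
) -> BaselineHazard:
    """Self-consistent baseline jumps at fixed ``beta``."""
    ctx = LikelihoodContext(sample, weights, link)
    jumps = ctx.solve_baseline(np.asarray(beta, dtype=float), baseline.jumps)
    return replace(baseline, jumps=jumps)


def weighted_loglik(
    beta: np.ndarray,
    baseline: BaselineHazard,
    sample: CompetingRisksSample,
    weights: WeightMatrix,
    link: LinkFunction,
) -> float:
    ctx = LikelihoodContext(sample, weights, link)
    return ctx.loglik(np.asarray(beta, dtype=float), baseline.jumps)


def loglik_gradient(
    beta: np.ndarray,
    baseline: BaselineHazard,
    sample: CompetingRisksSample,
    weights: WeightMatrix,
    link: LinkFunction,
) -> np.ndarray:
    ctx = LikelihoodContext(sample, weights, link)
    return ctx.gradient(np.asarray(beta, dtype=float), baseline.jumps)
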