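"""Inverse probability of censoring weighting (IPCW).

The weighted likelihood keeps subjects who failed from a competing
cause in the pseudo-risk set after their event; their contribution at a
later time ``t`` is discounted by the estimated probability of remaining
uncensored, ``w_i(t) = I(C_i >= T_i ^ t) * G(t-) / G((T_i ^ t)-)``,
where ``G`` is the product-limit (Kaplan-Meier) estimator of the
censoring survival function ``P(C > t)``.

Left limits are used when evaluating ``G`` at event times so that a
subject censored exactly at an event time still contributes there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sksurv.nonparametric import CensoringDistributionEstimator

from .datamodel import CompetingRisksSample

__all__ = [
    "CensoringSurvival",
    "WeightMatrix",
    "fit_censoring_survival",
    "compute_weights",
    "pseudo_risk_size",
]

#: floor applied to G in denominators to avoid blow-ups in heavy-censoring tails
G_FLOOR = 1e-10


@dataclass(frozen=True)
class CensoringSurvival:
    """Right-continuous step estimate of ``G(t) = P(C > t)``.

    ``grid`` holds the sorted distinct observed times, ``survival`` the
    step values just after each grid point; ``G(t) = 1`` before the first
    grid time.
    """

    grid: np.ndarray
    survival: np.ndarray

    def at(self, t) -> np.ndarray:
        """Right-continuous evaluation ``G(t)``."""
        idx = np.searchsorted(self.grid, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([1.0], self.survival))
        return vals[idx]

    def at_left(self, t) -> np.ndarray:
        """Left limit ``G(t-)``."""
        idx = np.searchsorted(self.grid, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate(([1.0], self.survival))
        return vals[idx]


def fit_censoring_survival(sample: CompetingRisksSample) -> CensoringSurvival:
    """Product-limit estimator of the censoring distribution.

    Censoring is treated as the event and all failures (any cause) as
    censored-for-G; with no censored subjects ``G`` is identically 1.
    """
    if np.all(sample.delta == 1):
        return CensoringSurvival(grid=np.sort(np.unique(sample.times)),
                                 survival=np.ones(len(np.unique(sample.times))))
    y = np.empty(sample.n, dtype=[("event", "?"), ("time", "f8")])
    y["event"] = sample.delta.astype(bool)  # True = failure; estimator flips it
    y["time"] = sample.times
    est = CensoringDistributionEstimator().fit(y)
    grid = np.asarray(est.unique_time_, dtype=float)
    prob = np.asarray(est.prob_, dtype=float)
    keep = np.isfinite(grid)  # drop the -inf anchor point
    return CensoringSurvival(grid=grid[keep], survival=prob[keep])


@dataclass(frozen=True)
class WeightMatrix:
    """IPCW weights ``w_i(t_j)`` on the ordered cause-1 event grid.

    Rows are subjects, columns the ordered cause-1 event times.  Entries
    lie in [0, 1]: 1 while the subject is under observation, 0 for a
    censored subject after its censoring time, and the survival ratio
    ``G(t-)/G(X_i-)`` for a failed subject after its event.
    """

    eval_times: np.ndarray
    weights: np.ndarray  # (n, m)


def compute_weights(
    sample: CompetingRisksSample,
    ghat: CensoringSurvival,
    eval_times: np.ndarray | None = None,
) -> WeightMatrix:
    """Build the ``n x m`` IPCW weight matrix at the cause-1 event grid."""
    if eval_times is None:
        eval_times = sample.cause1_event_times()
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(np.diff(eval_times) < 0):
        raise ValueError("eval_times must be sorted ascending")
    X = sample.times
    g_t = ghat.at_left(eval_times)  # (m,)
    g_x = np.maximum(ghat.at_left(X), G_FLOOR)  # (n,)
    # pre-event (t <= X_i): weight 1; post-event: depends on delta
    pre = X[:, None] >= eval_times[None, :]
    post_ratio = np.clip(g_t[None, :] / g_x[:, None], 0.0, 1.0)
    w = np.where(pre, 1.0, np.where(sample.delta[:, None] == 1, post_ratio, 0.0))
    # beyond the support of G (G(t-) == 0) nothing can be reweighted
    w[:, g_t <= G_FLOOR] = np.where(pre[:, g_t <= G_FLOOR], 1.0, 0.0)
    return WeightMatrix(eval_times=eval_times, weights=w)


def pseudo_risk_size(sample: CompetingRisksSample, ghat: CensoringSurvival, t: float) -> float:
    """Expected number of subjects in the pseudo-risk set at ``t``.

    ``sum_i I(X_i >= t) + sum_i I(X_i < t, delta_i = 1, eps_i != 1) *
    G(t-)/G(X_i-)`` -- the denominator of the covariate-free
    Nelson-Aalen-type increment of the subdistribution hazard.
    """
    X = sample.times
    at_risk = float(np.sum(X >= t))
    comp = (X < t) & (sample.delta == 1) & (sample.cause != 1)
    if not np.any(comp):
        return at_risk
    g_t = float(ghat.at_left(t))
    g_x = np.maximum(ghat.at_left(X[comp]), G_FLOOR)
    return at_risk + float(np.sum(np.clip(g_t / g_x, 0.0, 1.0)))
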