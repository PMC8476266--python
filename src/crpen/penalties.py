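"""Sparsity penalties: adaptive LASSO, adaptive elastic net, SCAD, MCP
and the ridge-augmented SCAD-L2 / MCP-L2 variants.

All penalties are additive over coordinates.  The L1-type part is
characterised by its derivative ``p'(|b|)``:

* adaptive LASSO: ``p'(|b|) = lam * v_j`` with data-driven weights
  ``v_j = 1/|bhat_j|`` from univariate unpenalized fits;
* SCAD (alpha > 2): ``lam`` on ``[0, lam]``, linear decay to zero at
  ``alpha*lam``, zero beyond;
* MCP (gamma > 1): ``(lam - |b|/gamma)_+``.

The ``*_l2`` families and the adaptive elastic net append a ridge term
``lam2 * b^2`` per coordinate to induce a grouping effect among highly
correlated covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PenaltySpec", "penalty_value", "penalty_derivative", "penalty_second_derivative",
           "adaptive_weights_from_marginal_fits", "FAMILIES"]

FAMILIES = ("alasso", "aenet", "scad", "scad_l2", "mcp", "mcp_l2")
ADAPTIVE_FAMILIES = ("alasso", "aenet")
RIDGE_FAMILIES = ("aenet", "scad_l2", "mcp_l2")

#: cap for adaptive weights when a marginal estimate is numerically zero
ADAPTIVE_WEIGHT_CAP = 1e6


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its tuning constants.

    ``lambda1`` is the sparsity level; ``lambda2`` the ridge level (only
    used by the ridge-augmented families); ``scad_a`` and ``mcp_gamma``
    the concavity knobs (SCAD requires ``a > 2``, MCP ``gamma > 1``).
    """

    family: str
    lambda1: float = 0.0
    lambda2: float = 0.0
    scad_a: float = 3.7
    mcp_gamma: float = 3.0
    adaptive_weights: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}; valid: {FAMILIES}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda values must be nonnegative")
        if self.scad_a <= 2:
            raise ValueError("SCAD tuning constant must exceed 2")
        if self.mcp_gamma <= 1:
            raise ValueError("MCP tuning constant must exceed 1")
        if self.adaptive_weights is not None:
            w = np.asarray(self.adaptive_weights, dtype=float)
            if np.any(~np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("adaptive weights must be finite and positive")
            object.__setattr__(self, "adaptive_weights", w)

    @property
    def is_adaptive(self) -> bool:
        return self.family in ADAPTIVE_FAMILIES

    @property
    def has_ridge(self) -> bool:
        return self.family in RIDGE_FAMILIES

    def with_lambda(self, lambda1: float, lambda2: float | None = None) -> "PenaltySpec":
        if lambda2 is None:
            lambda2 = self.lambda2
        return replace(self, lambda1=lambda1, lambda2=lambda2)

    def weights_for(self, d: int) -> np.ndarray:
        if self.is_adaptive:
            if self.adaptive_weights is None:
                raise ValueError(f"{self.family} requires adaptive_weights")
            return self.adaptive_weights
        return np.ones(d)


def _l1_part_value(spec: PenaltySpec, ab: np.ndarray) -> np.ndarray:
    lam = spec.lambda1
    if spec.family in ADAPTIVE_FAMILIES:
        return lam * spec.weights_for(ab.size) * ab
    if spec.family in ("scad", "scad_l2"):
        a = spec.scad_a
        low = ab <= lam
        mid = (ab > lam) & (ab <= a * lam)
        val = np.where(low, lam * ab, 0.0)
        val = np.where(mid, (2 * a * lam * ab - ab**2 - lam**2) / (2 * (a - 1)), val)
        val = np.where(ab > a * lam, lam**2 * (a + 1) / 2, val)
        return val
    # mcp / mcp_l2
    g = spec.mcp_gamma
    inside = ab <= g * lam
    return np.where(inside, lam * ab - ab**2 / (2 * g), 0.5 * g * lam**2)


def penalty_value(spec: PenaltySpec, beta: np.ndarray) -> float:
    """Total penalty ``sum_j p_lam(|b_j|) + lam2 * sum_j b_j^2``."""
    ab = np.abs(np.asarray(beta, dtype=float))
    total = float(np.sum(_l1_part_value(spec, ab)))
    if spec.lambda2 > 0:
        total += float(spec.lambda2 * np.sum(ab**2))
    return total


def penalty_derivative(spec: PenaltySpec, abs_beta, include_ridge: bool = True):
    """``p'(|b|)`` (plus ``2*lam2*|b|`` when ``include_ridge``).

    Accepts scalars or arrays; for adaptive families an array argument
    must have length d (one weight per coordinate).
    """
    ab = np.asarray(abs_beta, dtype=float)
    lam = spec.lambda1
    if spec.family in ADAPTIVE_FAMILIES:
        v = spec.weights_for(ab.size if ab.ndim else 1)
        der = lam * (v if ab.ndim else float(v[0] if np.ndim(v) else v))
        der = np.broadcast_to(np.asarray(der, dtype=float), ab.shape).copy() if ab.ndim else der
    elif spec.family in ("scad", "scad_l2"):
        a = spec.scad_a
        der = np.where(ab <= lam, lam, np.maximum(a * lam - ab, 0.0) / (a - 1))
    else:  # mcp / mcp_l2
        der = np.maximum(lam - ab / spec.mcp_gamma, 0.0)
    der = np.asarray(der, dtype=float)
    if include_ridge and spec.lambda2 > 0:
        der = der + 2.0 * spec.lambda2 * ab
    return der if np.ndim(abs_beta) else float(der)


def penalty_second_derivative(spec: PenaltySpec, abs_beta, include_ridge: bool = True):
    """``p''(|b|)`` where defined (0 at kink points), plus ``2*lam2``."""
    ab = np.asarray(abs_beta, dtype=float)
    lam = spec.lambda1
    if spec.family in ADAPTIVE_FAMILIES:
        der2 = np.zeros_like(ab)
    elif spec.family in ("scad", "scad_l2"):
        a = spec.scad_a
        der2 = np.where((ab > lam) & (ab < a * lam), -1.0 / (a - 1), 0.0)
    else:
        der2 = np.where(ab < spec.mcp_gamma * lam, -1.0 / spec.mcp_gamma, 0.0)
    if include_ridge and spec.lambda2 > 0:
        der2 = der2 + 2.0 * spec.lambda2
    return der2 if np.ndim(abs_beta) else float(der2)


def adaptive_weights_from_marginal_fits(sample, weights=None, link=None, max_iter: int = 25,
                                        tol: float = 1e-8) -> np.ndarray:
    """Data-driven weights ``v_j = 1/|bhat_j|`` from univariate fits.

    Each covariate is fitted alone by the unpenalized weighted
    likelihood.  For the identity link the profile likelihood equals the
    weighted Fine-Gray partial likelihood up to a constant, so the d
    scalar Newton iterations are run simultaneously on its score and
    information (one matrix product per quantity per iteration).
    Estimates below 1e-6 in magnitude (including non-convergent fits)
    are capped at ``v_j = 1e6``.
    """
    from .likelihood import LikelihoodContext  # local import to avoid cycle

    if isinstance(sample, LikelihoodContext):
        ctx = sample
    else:
        ctx = LikelihoodContext(sample, weights, link)
    Z = ctx.Z
    n, d = Z.shape
    # weighted pseudo-risk indicator r_ij = I(X_i >= t_j) + w_ij * I(post-event, eps>=2)
    R = _pseudo_risk_matrix(ctx)
    ev = ctx.subj_of_event
    z_ev_sum = Z[ev].sum(axis=0)  # (d,)
    beta = np.zeros(d)
    for _ in range(max_iter):
        E = np.exp(np.clip(Z * beta[None, :], -500, 500))  # (n, d)
        S0 = R.T @ E  # (m, d)
        S1 = R.T @ (Z * E)
        S2 = R.T @ (Z**2 * E)
        mu = S1 / S0
        score = z_ev_sum - mu.sum(axis=0)
        info = (S2 / S0 - mu**2).sum(axis=0)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        logger.warning("marginal fits: Newton iterations hit the cap; capping weights")
    ab = np.abs(beta)
    v = np.where(ab < 1e-6, ADAPTIVE_WEIGHT_CAP, 1.0 / np.maximum(ab, 1e-6))
    return v


def _pseudo_risk_matrix(ctx) -> np.ndarray:
    """(n, m) weighted pseudo-risk indicator used by marginal fits."""
    X = ctx.sample.times
    R = (X[:, None] >= ctx.grid[None, :]).astype(float)
    if ctx.i2.size:
        R[ctx.i2] += ctx.W2  # W2 is already masked to post-event columns
    return R
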