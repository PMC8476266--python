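"""Core domain types for right-censored competing-risks data.

A subject contributes an observed time ``X_i = min(T_i, C_i)``, a
non-censoring indicator ``delta_i``, a cause label ``eps_i`` (0 when
censored, 1 for the event of interest, >= 2 for competing events) and a
row of time-fixed covariates ``Z_i``.  The transformation link ``g``
maps the covariate-integrated baseline into the cumulative
subdistribution hazard ``A(t | z) = g( exp(b'z) * A0(t) )``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompetingRisksSample",
    "LinkFunction",
    "SimDesign",
    "validate_sample",
    "read_sample_csv",
    "write_sample_csv",
]


class ValidationError(ValueError):
    """Raised when raw competing-risks records violate an invariant."""


@dataclass(frozen=True)
class CompetingRisksSample:
    """Subject-level competing-risks data.

    Attributes
    ----------
    times : (n,) positive observed times ``X_i``.
    delta : (n,) 0/1 event indicator (1 = any failure observed).
    cause : (n,) integer cause labels; 0 iff censored.
    covariates : (n, d) real matrix of time-fixed covariates.
    tau : administrative horizon; defaults to the maximum observed time.
    """

    times: np.ndarray
    delta: np.ndarray
    cause: np.ndarray
    covariates: np.ndarray
    tau: float = field(default=np.nan)

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=int))
        object.__setattr__(self, "cause", np.asarray(self.cause, dtype=int))
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        object.__setattr__(self, "covariates", cov)
        if np.isnan(self.tau):
            object.__setattr__(self, "tau", float(self.times.max()))

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def d(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_cause1(self) -> int:
        return int(np.sum(self.cause == 1))

    def cause1_event_times(self) -> np.ndarray:
        """Ordered (distinct, after tie-breaking) cause-1 event times."""
        return np.sort(self.times[self.cause == 1])

    def subset_covariates(self, idx) -> "CompetingRisksSample":
        return replace(self, covariates=self.covariates[:, np.atleast_1d(idx)])


def _break_cause1_ties(times: np.ndarray, cause: np.ndarray) -> np.ndarray:
    """Perturb tied cause-1 event times so the ordered grid is strict.

    The likelihood machinery requires distinct event times of interest.
    Exact ties are separated deterministically by rank-ordered offsets of
    magnitude 1e-9 times the smallest positive gap between observed times.
    """
    out = times.copy()
    c1 = np.flatnonzero(cause == 1)
    t1 = out[c1]
    uniq, counts = np.unique(t1, return_counts=True)
    if np.all(counts == 1):
        return out
    gaps = np.diff(np.unique(out))
    eps = 1e-9 * (gaps[gaps > 0].min() if gaps.size else 1.0)
    for t, c in zip(uniq[counts > 1], counts[counts > 1]):
        tied = c1[np.flatnonzero(t1 == t)]
        out[tied] = t + eps * np.arange(c)
    warnings.warn(
        "tied cause-1 event times were separated by deterministic "
        f"perturbations of magnitude {eps:.3g}",
        stacklevel=3,
    )
    return out


def validate_sample(raw) -> CompetingRisksSample:
    """Validate tabular records and return a typed sample.

    Parameters
    ----------
    raw : DataFrame (or mapping convertible to one) with columns
        ``time``, ``status``, ``cause`` and covariate columns
        ``z1..zd`` (any remaining columns are taken as covariates, in
        order).

    Raises
    ------
    ValidationError with a distinct message for each violated invariant.
    """
    df = pd.DataFrame(raw)
    for col in ("time", "status", "cause"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing values in rows {bad[:10]}")
    covcols = [c for c in df.columns if c not in ("time", "status", "cause")]
    if not covcols:
        raise ValidationError("no covariate columns found")
    times = df["time"].to_numpy(dtype=float)
    delta = df["status"].to_numpy()
    cause = df["cause"].to_numpy()
    if not np.isin(delta, [0, 1]).all():
        raise ValidationError("status must be 0 or 1")
    if np.any(times <= 0):
        rows = np.flatnonzero(times <= 0).tolist()
        raise ValidationError(f"nonpositive observed times in rows {rows[:10]}")
    delta = delta.astype(int)
    cause = cause.astype(int)
    if np.any(cause < 0):
        raise ValidationError("negative cause labels")
    if np.any((delta == 0) & (cause != 0)):
        rows = np.flatnonzero((delta == 0) & (cause != 0)).tolist()
        raise ValidationError(f"cause label on censored record (rows {rows[:10]})")
    if np.any((delta == 1) & (cause == 0)):
        rows = np.flatnonzero((delta == 1) & (cause == 0)).tolist()
        raise ValidationError(f"event indicator without cause label (rows {rows[:10]})")
    if len(times) < 2:
        raise ValidationError("need at least 2 subjects")
    if not np.any(cause == 1):
        raise ValidationError("no events of interest (cause 1) in the data")
    times = _break_cause1_ties(times, cause)
    Z = df[covcols].to_numpy(dtype=float)
    return CompetingRisksSample(times=times, delta=delta, cause=cause, covariates=Z)


def read_sample_csv(path) -> CompetingRisksSample:
    """Read the documented CSV schema ``time,status,cause,z1,...,zd``."""
    return validate_sample(pd.read_csv(path))


def write_sample_csv(sample: CompetingRisksSample, path) -> None:
    df = pd.DataFrame({"time": sample.times, "status": sample.delta, "cause": sample.cause})
    for j in range(sample.d):
        df[f"z{j + 1}"] = sample.covariates[:, j]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transformation links


@dataclass(frozen=True)
class LinkFunction:
    """Transformation link ``g`` with derivatives up to third order.

    Two parametric families are supported on ``[0, inf)``:

    * ``box_cox`` with parameter ``rho >= 0``:
      ``g(x) = ((1+x)**rho - 1)/rho`` (``rho -> 0`` gives ``log(1+x)``).
      ``rho = 1`` is the identity, i.e. the Fine-Gray proportional
      subdistribution hazards model.
    * ``logarithmic`` with parameter ``r >= 0``:
      ``g(x) = log(1+r*x)/r`` (``r -> 0`` gives the identity).  ``r = 1``
      is ``log(1+x)``, the proportional-odds subdistribution model.

    Both limits are implemented analytically.
    """

    kind: str
    parameter: float

    def __post_init__(self):
        if self.kind not in ("box_cox", "logarithmic"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.parameter < 0:
            raise ValueError("link parameter must be nonnegative")

    # -- named instances ----------------------------------------------------
    @staticmethod
    def fine_gray() -> "LinkFunction":
        """Identity link g(x) = x (proportional subdistribution hazards)."""
        return LinkFunction("box_cox", 1.0)

    @staticmethod
    def prop_odds() -> "LinkFunction":
        """g(x) = log(1 + x) (proportional-odds subdistribution model)."""
        return LinkFunction("logarithmic", 1.0)

    @property
    def is_identity(self) -> bool:
        return (self.kind == "box_cox" and self.parameter == 1.0) or (
            self.kind == "logarithmic" and self.parameter == 0.0
        )

    def g(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameter
        if self.kind == "box_cox":
            if p == 0.0:
                return np.log1p(x)
            if p == 1.0:
                return x + 0.0
            return (np.power(1.0 + x, p) - 1.0) / p
        if p == 0.0:
            return x + 0.0
        return np.log1p(p * x) / p

    def dg(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameter
        if self.kind == "box_cox":
            if p == 1.0:
                return np.ones_like(x)
            return np.power(1.0 + x, p - 1.0)
        if p == 0.0:
            return np.ones_like(x)
        return 1.0 / (1.0 + p * x)

    def d2g(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameter
        if self.kind == "box_cox":
            if p == 1.0:
                return np.zeros_like(x)
            return (p - 1.0) * np.power(1.0 + x, p - 2.0)
        if p == 0.0:
            return np.zeros_like(x)
        return -p / (1.0 + p * x) ** 2

    def d3g(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameter
        if self.kind == "box_cox":
            if p == 1.0:
                return np.zeros_like(x)
            return (p - 1.0) * (p - 2.0) * np.power(1.0 + x, p - 3.0)
        if p == 0.0:
            return np.zeros_like(x)
        return 2.0 * p**2 / (1.0 + p * x) ** 3

    def __repr__(self):  # pragma: no cover - cosmetic
        if self.is_identity:
            return "LinkFunction(identity / Fine-Gray)"
        if self.kind == "logarithmic" and self.parameter == 1.0:
            return "LinkFunction(log(1+x) / proportional odds)"
        return f"LinkFunction({self.kind}, {self.parameter})"


def parse_link(text: str) -> LinkFunction:
    """Parse ``fg``, ``po``, ``boxcox:<rho>`` or ``log:<r>``."""
    text = text.strip().lower()
    if text == "fg":
        return LinkFunction.fine_gray()
    if text == "po":
        return LinkFunction.prop_odds()
    if text.startswith("boxcox:"):
        return LinkFunction("box_cox", float(text.split(":", 1)[1]))
    if text.startswith("log:"):
        return LinkFunction("logarithmic", float(text.split(":", 1)[1]))
    raise ValueError(f"unknown link spec {text!r}; use fg, po, boxcox:<rho> or log:<r>")


# ---------------------------------------------------------------------------
# simulation design


@dataclass(frozen=True)
class SimDesign:
    """Configuration of one synthetic competing-risks scenario.

    ``k_ratio`` is the cause-1 mixture mass at ``z = 0`` (the generator
    leaves mass ``1 - k`` at infinity for the event of interest);
    ``cens_bound`` is the upper bound ``a`` of the Uniform(0, a)
    censoring distribution; ``rho_corr`` is the AR(1) covariate
    correlation parameter (ignored for the grouped design).
    """

    n: int
    d: int
    rho_corr: float
    k_ratio: float
    cens_bound: float
    beta1: np.ndarray
    beta2: np.ndarray
    design: str = "ar1"  # {"ar1", "grouped"}
    link: LinkFunction = field(default_factory=LinkFunction.fine_gray)
    seed: int = 0
    #: linear predictor of the conditional cause-2 exponential rate:
    #: "beta1" (rate exp(b1'z)) or "beta2" (rate exp(b2'z))
    cause2_rate: str = "beta1"

    def __post_init__(self):
        object.__setattr__(self, "beta1", np.asarray(self.beta1, dtype=float))
        object.__setattr__(self, "beta2", np.asarray(self.beta2, dtype=float))
        if not (0.0 < self.k_ratio < 1.0):
            raise ValueError("k_ratio must lie in (0, 1)")
        if not (0.0 <= self.rho_corr < 1.0):
            raise ValueError("rho_corr must lie in [0, 1)")
        if self.design not in ("ar1", "grouped"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.cause2_rate not in ("beta1", "beta2"):
            raise ValueError(f"unknown cause2_rate {self.cause2_rate!r}")
        if self.beta1.shape != (self.d,) or self.beta2.shape != (self.d,):
            raise ValueError("beta vectors must have length d")

    @property
    def true_support(self) -> np.ndarray:
        return np.flatnonzero(self.beta1 != 0.0)
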