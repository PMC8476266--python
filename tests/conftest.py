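"""Shared fixtures: small hand-built and simulated competing-risks samples."""

import numpy as np
import pytest

from crpen import (
    CompetingRisksSample,
    LikelihoodContext,
    LinkFunction,
    compute_weights,
    fit_censoring_survival,
)
from crpen.simulate import make_design, simulate_dataset


@pytest.fixture
def tiny_sample():
    """Six subjects: cause-1 events, a competing event, censoring."""
    return CompetingRisksSample(
        times=np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5]),
        delta=np.array([1, 1, 0, 1, 1, 0]),
        cause=np.array([1, 2, 0, 1, 1, 0]),
        covariates=np.array([[0.5, -1.0], [1.0, 0.3], [-0.2, 0.8],
                             [0.0, -0.5], [-1.2, 0.1], [0.7, 1.1]]),
    )


@pytest.fixture
def no_censoring_sample():
    """Four cause-1 events, no censoring, no competing cause."""
    return CompetingRisksSample(
        times=np.array([1.0, 2.0, 3.0, 4.0]),
        delta=np.ones(4, dtype=int),
        cause=np.ones(4, dtype=int),
        covariates=np.array([[0.3], [-0.6], [1.1], [0.2]]),
    )


def build_context(sample, link=None):
    link = link or LinkFunction.fine_gray()
    ghat = fit_censoring_survival(sample)
    wm = compute_weights(sample, ghat)
    return LikelihoodContext(sample, wm, link)


@pytest.fixture
def sim_sample():
    """Moderate simulated dataset from the main subdistribution design."""
    design = make_design("table1", n=120, d=5, k=0.5, seed=11)
    return simulate_dataset(design).sample


def random_sample(rng, n=40, d=3, cens_frac=0.3, comp_frac=0.3):
    """Small random competing-risks dataset for property tests."""
    times = rng.exponential(size=n) + 0.05
    u = rng.uniform(size=n)
    delta = (u > cens_frac).astype(int)
    cause = np.where(delta == 0, 0, np.where(rng.uniform(size=n) < comp_frac, 2, 1))
    if not np.any(cause == 1):  # ensure at least one event of interest
        cause[np.argmax(delta)] = 1
        delta[np.argmax(delta)] = 1
    Z = rng.normal(size=(n, d))
    return CompetingRisksSample(times=times, delta=delta, cause=cause, covariates=Z)
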