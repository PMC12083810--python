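"""Shared fixtures and the exact-quadrature oracle for sampler validation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from bronchbayes import McmcSettings, canbest_fixture, reference_priors
from bronchbayes.inference import SITE_MU_LOC, SITE_MU_SCALE, SITE_TAU_SCALE


@pytest.fixture(scope="session")
def canbest():
    return canbest_fixture()


@pytest.fixture(scope="session")
def archetypes():
    return reference_priors()


@pytest.fixture()
def fast_settings():
    """Small draw budget for unit tests of sampler plumbing (not accuracy)."""
    return McmcSettings(draws=4000, burn_in=2000, chains=2, seed=123)


def exact_two_arm_posterior(prior, treated_events, treated_n, control_events, control_n):
    """Exact single-site two-arm posterior of the log-RR by 2-d quadrature.

    Computes the marginal prior on the site intercept alpha by integrating
    the hierarchy (alpha ~ N(mu, tau^2), mu ~ N, tau ~ half-N) on a grid,
    then the joint posterior of (alpha, beta) under the exact binomial
    likelihood with the log-link support constraint alpha + beta < 0.
    Returns (median_rr, tail_prob_fn) where tail_prob_fn(t) = P(RR < t).
    Entirely sampler-free: the independent oracle for the MCMC fit.
    """
    mus = np.linspace(SITE_MU_LOC - 8, SITE_MU_LOC + 8, 401)
    taus = np.linspace(5e-4, 5 * SITE_TAU_SCALE, 401)
    wmu = stats.norm.pdf(mus, SITE_MU_LOC, SITE_MU_SCALE)
    wtau = 2 * stats.norm.pdf(taus, 0, SITE_TAU_SCALE)
    alphas = np.linspace(-5.0, -0.05, 1201)
    p_alpha = np.zeros_like(alphas)
    for t, wt in zip(taus, wtau):
        p_alpha += wt * (stats.norm.pdf(alphas[:, None], mus[None, :], t) * wmu).sum(
            axis=1
        )
    betas = np.linspace(-2.5, 1.2, 2001)
    log_post = (
        np.log(p_alpha)[:, None]
        + stats.norm.logpdf(betas[None, :], np.log(prior.median_rr), prior.sd_log)
    )
    la, lb = alphas[:, None], betas[None, :]
    cell = la + lb
    a, n1, c, n0 = treated_events, treated_n, control_events, control_n
    loglik = np.where(
        cell < 0,
        a * cell
        + (n1 - a) * np.log1p(-np.exp(np.minimum(cell, -1e-12)))
        + c * la
        + (n0 - c) * np.log1p(-np.exp(la)),
        -np.inf,
    )
    post = np.exp(log_post + loglik - (log_post + loglik).max())
    pb = post.sum(axis=0)
    pb /= pb.sum()
    cdf = np.cumsum(pb)
    median_rr = float(np.exp(np.interp(0.5, cdf, betas)))

    def tail_prob(t: float) -> float:
        return float(np.interp(np.log(t), betas, cdf))

    return median_rr, tail_prob


@pytest.fixture(scope="session")
def two_arm_oracle():
    return exact_two_arm_posterior
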