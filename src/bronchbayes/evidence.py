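"""Data-driven priors: hierarchical pooling of historical two-arm studies.

Historical randomized studies comparing an active arm to control are
summarized by their log relative risk and its standard error, pooled with a
Bayesian normal-normal random-effects model (study effects drawn around a
common mean with between-study SD tau), and the pooled distribution is then
down-weighted into a prior.  A weight w in (0, 1] represents the relative
contribution of one historical participant versus one current-trial
participant, and acts on the prior variance: sd_log -> sd_log / sqrt(w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import emcee
import numpy as np
import pandas as pd

from .inference import McmcSettings, NormalSummary
from .priors import PriorSpec

__all__ = [
    "StudySummary",
    "PooledEvidence",
    "study_log_rr",
    "pool_studies",
    "apply_prior_weight",
    "read_studies_csv",
]

# Uninformative hyperpriors for the pooling model.
_POOL_MU_SCALE = 10.0  # mu ~ Normal(0, 10^2) on the log-RR scale
_POOL_TAU_SCALE = 1.0  # tau ~ Half-Normal(1)


def _pool_moves():
    import emcee.moves as mv

    return [(mv.DEMove(), 1.0)]


@dataclass(frozen=True)
class StudySummary:
    """Two-arm binomial counts from one historical study."""

    study_id: str
    treated_events: int
    treated_n: int
    control_events: int
    control_n: int

    def __post_init__(self) -> None:
        for arm, events, n in (
            ("treated", self.treated_events, self.treated_n),
            ("control", self.control_events, self.control_n),
        ):
            if n <= 0:
                raise ValueError(f"{self.study_id}: {arm} arm has n = {n}, must be > 0")
            if events < 0:
                raise ValueError(f"{self.study_id}: {arm} events must be >= 0")
            if events > n:
                raise ValueError(
                    f"{self.study_id}: {arm} events ({events}) exceed n ({n})"
                )


@dataclass(frozen=True)
class PooledEvidence:
    """Posterior summary of the random-effects pooled log-RR.

    ``mean_log_rr``/``sd_log`` describe the pooled effect mu; ``tau`` is the
    posterior median between-study SD.
    """

    mean_log_rr: float
    sd_log: float
    tau: float

    def __post_init__(self) -> None:
        if not self.sd_log > 0:
            raise ValueError(f"sd_log must be > 0, got {self.sd_log!r}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau!r}")


def study_log_rr(study: StudySummary) -> NormalSummary:
    """Per-study log-RR estimate with its delta-method standard error.

    Zero cells get the standard 0.5 continuity correction applied to all
    four cells of that study's 2x2 table, flagged on the returned summary.
    """
    a, n1 = study.treated_events, study.treated_n
    c, n0 = study.control_events, study.control_n
    corrected = 0 in (a, n1 - a, c, n0 - c)
    if corrected:
        a, n1, c, n0 = a + 0.5, n1 + 0.5, c + 0.5, n0 + 0.5
    mean = math.log((a / n1) / (c / n0))
    sd = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return NormalSummary(mean_log_rr=mean, sd_log=sd, continuity_corrected=corrected)


def _pool_log_prob(y: np.ndarray, se: np.ndarray, tau_scale: float):
    """Log posterior of (mu, tau) with study effects marginalized out.

    Marginally y_i ~ Normal(mu, se_i^2 + tau^2), which is exact for the
    normal-normal hierarchy, so only two parameters need sampling.
    """

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, tau = theta[:, 0], theta[:, 1]
        out = np.full(theta.shape[0], -np.inf)
        ok = tau >= 0
        if np.any(ok):
            var = se**2 + tau[ok, None] ** 2
            ll = -0.5 * ((y - mu[ok, None]) ** 2 / var + np.log(var)).sum(axis=1)
            lp = -0.5 * (mu[ok] / _POOL_MU_SCALE) ** 2
            if tau_scale > 0:
                lp += -0.5 * (tau[ok] / tau_scale) ** 2
            out[ok] = ll + lp
        return out

    return log_prob


def pool_studies(
    studies: Sequence[StudySummary],
    settings: McmcSettings = McmcSettings(draws=20_000, burn_in=10_000, chains=2),
    tau_prior_scale: float = _POOL_TAU_SCALE,
    fix_tau: float | None = None,
) -> PooledEvidence:
    """Pool historical studies with a Bayesian random-effects model.

    Study-level log-RRs (continuity-corrected where needed) are modelled as
    y_i ~ Normal(theta_i, se_i^2), theta_i ~ Normal(mu, tau^2), with
    uninformative hyperpriors mu ~ Normal(0, 10^2), tau ~ Half-Normal(1).
    Returns the posterior mean/SD of mu and the posterior median of tau.

    ``fix_tau`` pins the between-study SD (0 gives the fixed-effect model,
    useful as a closed-form cross-check); ``tau_prior_scale`` rescales the
    half-normal heterogeneity prior.
    """
    if len(studies) == 0:
        raise ValueError("pool_studies requires at least one study")
    effects = [study_log_rr(s) for s in studies]
    y = np.array([e.mean_log_rr for e in effects])
    se = np.array([e.sd_log for e in effects])

    if fix_tau is not None:
        if fix_tau < 0:
            raise ValueError("fix_tau must be >= 0")
        # conjugate normal: precision-weighted pooling with known variances
        var = se**2 + fix_tau**2
        prec = (1.0 / var).sum() + 1.0 / _POOL_MU_SCALE**2
        mean = (y / var).sum() / prec
        return PooledEvidence(
            mean_log_rr=float(mean), sd_log=float(1.0 / math.sqrt(prec)), tau=fix_tau
        )

    log_prob = _pool_log_prob(y, se, tau_prior_scale)
    ndim, nwalkers = 2, 20
    retained = settings.retained
    keep_steps = -(-retained // nwalkers)
    burn_steps = -(-settings.burn_in // nwalkers)
    total_steps = keep_steps + burn_steps
    thin = max(1, -(-2000 // total_steps))

    seed_seq = np.random.SeedSequence((settings.seed, 0x9E3779B9))
    draws = []
    for child in seed_seq.spawn(settings.chains):
        rng = np.random.default_rng(child)
        start = np.column_stack(
            [
                y.mean() + 0.1 * rng.standard_normal(nwalkers),
                np.abs(0.2 + 0.05 * rng.standard_normal(nwalkers)),
            ]
        )
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True, moves=_pool_moves()
        )
        sampler._random = np.random.RandomState(
            child.generate_state(1, dtype=np.uint32)[0]
        )
        sampler.run_mcmc(start, total_steps, thin_by=thin, progress=False)
        draws.append(sampler.get_chain(discard=burn_steps).reshape(-1, ndim)[:retained])
    flat = np.concatenate(draws, axis=0)
    mu_draws, tau_draws = flat[:, 0], flat[:, 1]
    return PooledEvidence(
        mean_log_rr=float(np.mean(mu_draws)),
        sd_log=float(np.std(mu_draws, ddof=1)),
        tau=float(np.median(tau_draws)),
    )


def apply_prior_weight(pooled: PooledEvidence, w: float) -> PriorSpec:
    """Down-weight pooled evidence into a prior: sd_log -> sd_log / sqrt(w).

    The weight w in (0, 1] is the information one historical participant
    contributes relative to one current-trial participant; the pooled median
    RR is unchanged.
    """
    if not 0 < w <= 1:
        raise ValueError(f"weight must lie in (0, 1], got {w!r}")
    pct = f"{100 * w:g}% weighting"
    return PriorSpec(
        label=pct,
        median_rr=math.exp(pooled.mean_log_rr),
        sd_log=pooled.sd_log / math.sqrt(w),
    )


def read_studies_csv(path: str | Path) -> list[StudySummary]:
    """Read a historical-studies table (study_id, treated/control events and n)."""
    df = pd.read_csv(path)
    required = ["study_id", "treated_events", "treated_n", "control_events", "control_n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples():
        try:
            out.append(
                StudySummary(
                    study_id=str(row.study_id),
                    treated_events=int(row.treated_events),
                    treated_n=int(row.treated_n),
                    control_events=int(row.control_events),
                    control_n=int(row.control_n),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row.Index}: {exc}") from None
    return out
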