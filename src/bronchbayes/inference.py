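"""Site-adjusted hierarchical log-binomial model for a four-arm factorial trial.

The outcome model is a binomial GLM with a log link, so treatment
coefficients are log relative risks versus placebo:

    events[s, a] ~ Binomial(n[s, a], p[s, a])
    log p[s, a]  = alpha_s + beta_a,          beta_placebo = 0
    beta_a       ~ Normal(log median_rr_a, sd_log_a**2)     (the prior)
    alpha_s      ~ Normal(mu_site, tau_site**2)             (site adjustment)

The log link requires every fitted probability to stay below 1; parameter
vectors violating alpha_s + beta_a < 0 receive zero posterior support.
Sampling is by differential-evolution ensemble MCMC (emcee), with independent
ensembles playing the role of chains.  A closed-form conjugate
normal-normal posterior on the log-RR scale serves as an oracle for the
sampler on aggregate two-arm data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from .priors import PriorSpec

__all__ = [
    "ARMS",
    "CONTRAST_ARMS",
    "TrialDataset",
    "NormalSummary",
    "McmcSettings",
    "PosteriorSamples",
    "ConvergenceReport",
    "likelihood_summary",
    "conjugate_posterior",
    "fit_hierarchical_log_binomial",
    "check_convergence",
]

logger = logging.getLogger(__name__)

#: Arm labels in canonical order; "epidex" is the epinephrine+dexamethasone
#: combination arm and carries its own coefficient (no interaction term).
ARMS: tuple[str, ...] = ("placebo", "epi", "dex", "epidex")
CONTRAST_ARMS: tuple[str, ...] = ("epi", "dex", "epidex")

# Hyperpriors for the site-intercept hierarchy.  Weakly informative around
# plausible admission risks (placebo admission risk near 25%); the
# half-normal scale keeps between-site spread of log risk on the order of
# one unit or less.
SITE_MU_LOC = math.log(0.25)
SITE_MU_SCALE = 1.5
SITE_TAU_SCALE = 1.0

# Ensemble geometry: each chain is an independent ensemble whose walkers are
# flattened (step-major) into that chain's draws.  The ensemble is run for
# at least this many moves (internal thinning keeps retained-draw counts
# unchanged).  Differential-evolution proposals traverse the site-hierarchy
# funnel far faster than stretch moves; snooker moves are avoided because
# they pin the hierarchy scale against its zero boundary.
_MIN_ENSEMBLE_MOVES = 6000


def _default_moves():
    import emcee.moves as mv

    return [(mv.DEMove(), 1.0)]


@dataclass(frozen=True)
class TrialDataset:
    """Per-site, per-arm binomial counts with columns site, arm, n, events."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        required = ["site", "arm", "n", "events"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trial data missing columns {missing}")
        df = df[required]
        df["site"] = df["site"].astype(str)
        df["arm"] = df["arm"].astype(str)
        for row in df.itertuples():
            idx = row.Index
            if row.arm not in ARMS:
                raise ValueError(
                    f"row {idx}: unknown arm label {row.arm!r} (expected one of {ARMS})"
                )
            if row.n < 0 or int(row.n) != row.n:
                raise ValueError(f"row {idx}: n must be a non-negative integer")
            if row.events < 0 or int(row.events) != row.events:
                raise ValueError(f"row {idx}: events must be a non-negative integer")
            if row.events > row.n:
                raise ValueError(
                    f"row {idx}: events ({row.events}) exceed n ({row.n})"
                )
        df["n"] = df["n"].astype(int)
        df["events"] = df["events"].astype(int)
        if df.duplicated(subset=["site", "arm"]).any():
            dup = df[df.duplicated(subset=["site", "arm"], keep=False)]
            raise ValueError(f"duplicate (site, arm) rows:\n{dup}")
        if df["site"].nunique() < 1:
            raise ValueError("trial data must contain at least one site")
        if "placebo" not in set(df["arm"]):
            raise ValueError("trial data must contain a placebo arm")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls, rows: Sequence[tuple[str, str, int, int]]
    ) -> "TrialDataset":
        return cls(pd.DataFrame(rows, columns=["site", "arm", "n", "events"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialDataset":
        df = pd.read_csv(path)
        try:
            return cls(df)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    # -- views --------------------------------------------------------------

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.records["site"]))

    @property
    def arms(self) -> list[str]:
        present = set(self.records["arm"])
        return [a for a in ARMS if a in present]

    def arm_totals(self) -> pd.DataFrame:
        """Counts pooled over sites, one row per arm in canonical order."""
        tot = self.records.groupby("arm", sort=False)[["n", "events"]].sum()
        return tot.reindex([a for a in ARMS if a in tot.index])

    def collapse(self, arms: Sequence[str]) -> "TrialDataset":
        """Restrict to a subset of arms (placebo must be kept)."""
        keep = self.records[self.records["arm"].isin(set(arms))]
        return TrialDataset(keep.reset_index(drop=True))


@dataclass(frozen=True)
class NormalSummary:
    """A normal distribution on the log-RR scale (likelihood or posterior)."""

    mean_log_rr: float
    sd_log: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.sd_log > 0:
            raise ValueError(f"sd_log must be > 0, got {self.sd_log!r}")
        if not np.isfinite(self.mean_log_rr):
            raise ValueError(f"mean_log_rr must be finite, got {self.mean_log_rr!r}")


@dataclass(frozen=True)
class McmcSettings:
    """Per-chain draw budget: ``draws`` total with the first ``burn_in`` discarded."""

    draws: int = 20_000
    burn_in: int = 10_000
    chains: int = 4
    seed: int = 2024

    def __post_init__(self) -> None:
        if not (self.draws > self.burn_in >= 0):
            raise ValueError(
                f"need draws > burn_in >= 0, got draws={self.draws}, burn_in={self.burn_in}"
            )
        if self.chains < 1:
            raise ValueError(f"chains must be >= 1, got {self.chains}")

    @property
    def retained(self) -> int:
        return self.draws - self.burn_in


def likelihood_summary(
    treated_events: int, treated_n: int, control_events: int, control_n: int
) -> NormalSummary:
    """Normal approximation to the log-RR likelihood from a 2x2 table.

    mean = log[(a/n1)/(c/n0)], sd = sqrt(1/a - 1/n1 + 1/c - 1/n0).  Used by
    the conjugate oracle; zero event counts have no finite log-RR and are
    routed to the continuity-corrected per-study path instead.
    """
    a, n1, c, n0 = treated_events, treated_n, control_events, control_n
    if n1 <= 0 or n0 <= 0:
        raise ValueError("arm sizes must be positive")
    if a > n1 or c > n0:
        raise ValueError("events cannot exceed arm size")
    if a == 0 or c == 0:
        raise ValueError(
            "zero events in an arm: the log-RR is undefined; use the "
            "continuity-corrected study_log_rr path instead"
        )
    mean = math.log((a / n1) / (c / n0))
    sd = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return NormalSummary(mean_log_rr=mean, sd_log=sd)


def conjugate_posterior(prior: PriorSpec, lik: NormalSummary) -> NormalSummary:
    """Precision-weighted normal-normal posterior on the log-RR scale."""
    prec_prior = 1.0 / prior.sd_log**2
    prec_lik = 1.0 / lik.sd_log**2
    prec = prec_prior + prec_lik
    mean = (prec_prior * prior.mean_log_rr + prec_lik * lik.mean_log_rr) / prec
    return NormalSummary(mean_log_rr=mean, sd_log=math.sqrt(1.0 / prec))


# ---------------------------------------------------------------------------
# MCMC fit


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, shaped (chains, retained) per scalar parameter."""

    contrast_draws: dict[str, np.ndarray]
    site_draws: np.ndarray  # (chains, retained, n_sites)
    site_ids: list[str]
    hyper_draws: dict[str, np.ndarray]
    settings: McmcSettings
    warnings: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        first = next(iter(self.contrast_draws.values()))
        return first.shape[0] * first.shape[1]

    def log_rr(self, contrast: str) -> np.ndarray:
        """All retained log-RR draws for one contrast, flattened."""
        return self.contrast_draws[contrast].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            f"log_rr_{k}": v for k, v in self.contrast_draws.items()
        }
        posterior["site_intercept"] = self.site_draws
        posterior.update(self.hyper_draws)
        return az.from_dict(
            posterior=posterior, coords={"site": self.site_ids},
            dims={"site_intercept": ["site"]},
        )


def _build_design(data: TrialDataset, priors: Mapping[str, PriorSpec]):
    sites = data.sites
    contrasts = [a for a in CONTRAST_ARMS if a in data.arms]
    missing = [a for a in contrasts if a not in priors]
    if missing:
        raise ValueError(f"missing prior for contrast(s): {missing}")
    site_index = {s: i for i, s in enumerate(sites)}
    beta_index = {a: i for i, a in enumerate(contrasts)}
    rec = data.records
    s_idx = rec["site"].map(site_index).to_numpy()
    # placebo cells map to a dummy beta slot of exactly zero
    b_idx = rec["arm"].map(lambda a: beta_index.get(a, len(contrasts))).to_numpy()
    n = rec["n"].to_numpy(float)
    events = rec["events"].to_numpy(float)
    prior_mean = np.array([priors[a].mean_log_rr for a in contrasts])
    prior_sd = np.array([priors[a].sd_log for a in contrasts])
    return sites, contrasts, s_idx, b_idx, n, events, prior_mean, prior_sd


def _make_log_prob(n_sites, n_beta, s_idx, b_idx, n, events, prior_mean, prior_sd):
    """Vectorized log posterior over a (walkers, ndim) parameter block.

    Layout: [mu_site, tau_site, alpha_0..S-1, beta_0..K-1].
    """

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        tau = theta[:, 1]
        alpha = theta[:, 2 : 2 + n_sites]
        beta = theta[:, 2 + n_sites :]
        beta_ext = np.concatenate([beta, np.zeros((theta.shape[0], 1))], axis=1)

        logp_cells = alpha[:, s_idx] + beta_ext[:, b_idx]  # (walkers, cells)
        out = np.full(theta.shape[0], -np.inf)
        ok = (tau > 0) & np.all(logp_cells < 0, axis=1)
        if not np.any(ok):
            return out if theta.shape[0] > 1 else out[0]

        lp = logp_cells[ok]
        ll = events * lp + (n - events) * np.log1p(-np.exp(lp))
        total = ll.sum(axis=1)
        # hyperpriors and hierarchy
        total += -0.5 * ((mu[ok] - SITE_MU_LOC) / SITE_MU_SCALE) ** 2
        total += -0.5 * (tau[ok] / SITE_TAU_SCALE) ** 2
        a_centered = (alpha[ok] - mu[ok, None]) / tau[ok, None]
        total += np.sum(
            -0.5 * a_centered**2 - np.log(tau[ok, None]), axis=1
        )
        total += np.sum(
            -0.5 * ((beta[ok] - prior_mean) / prior_sd) ** 2, axis=1
        )
        out[ok] = total
        return out

    return log_prob


def _initial_walkers(
    rng: np.random.Generator,
    nwalkers: int,
    data: TrialDataset,
    contrasts: list[str],
    prior_mean: np.ndarray,
    log_prob,
) -> np.ndarray:
    """Start walkers in a small ball around crude moment estimates."""
    totals = data.arm_totals()
    p0 = (totals.loc["placebo", "events"] + 0.5) / (totals.loc["placebo", "n"] + 1.0)
    alpha0 = math.log(p0)
    beta0 = np.empty(len(contrasts))
    for i, a in enumerate(contrasts):
        pa = (totals.loc[a, "events"] + 0.5) / (totals.loc[a, "n"] + 1.0)
        beta0[i] = 0.5 * (math.log(pa / p0) + prior_mean[i])
    n_sites = len(data.sites)
    ndim = 2 + n_sites + len(contrasts)
    center = np.concatenate([[alpha0, 0.3], np.full(n_sites, alpha0), beta0])
    walkers = center + 0.03 * rng.standard_normal((nwalkers, ndim))
    walkers[:, 1] = np.abs(walkers[:, 1]) + 1e-3
    # resample any walker that starts outside the support (p >= 1)
    for _ in range(100):
        bad = ~np.isfinite(log_prob(walkers))
        if not np.any(bad):
            break
        walkers[bad] = center + 0.01 * rng.standard_normal((bad.sum(), ndim))
        walkers[bad, 1] = np.abs(walkers[bad, 1]) + 1e-3
    return walkers


def fit_hierarchical_log_binomial(
    data: TrialDataset,
    priors: Mapping[str, PriorSpec],
    settings: McmcSettings = McmcSettings(),
) -> PosteriorSamples:
    """Sample the posterior of the site-adjusted log-binomial model.

    ``priors`` maps each non-placebo arm present in ``data`` to its
    :class:`PriorSpec` on the RR versus placebo.  Each chain is an
    independent walker ensemble seeded from ``settings.seed``; identical
    settings yield identical draws.  A convergence warning (split R-hat >
    1.01 on any treatment contrast) is attached to the result, never
    silenced.
    """
    sites, contrasts, s_idx, b_idx, n, events, prior_mean, prior_sd = _build_design(
        data, priors
    )
    n_sites, n_beta = len(sites), len(contrasts)
    ndim = 2 + n_sites + n_beta
    nwalkers = max(20, 2 * ndim + 2)
    nwalkers += nwalkers % 2

    retained = settings.retained
    keep_steps = -(-retained // nwalkers)  # ceil
    burn_steps = -(-settings.burn_in // nwalkers)
    total_steps = keep_steps + burn_steps
    # cap the thinning multiplier so tiny exploratory budgets stay cheap
    thin = min(16, max(1, -(-_MIN_ENSEMBLE_MOVES // total_steps)))

    log_prob = _make_log_prob(
        n_sites, n_beta, s_idx, b_idx, n, events, prior_mean, prior_sd
    )

    seed_seq = np.random.SeedSequence(settings.seed)
    chain_draws = np.empty((settings.chains, retained, ndim))
    for chain, child in enumerate(seed_seq.spawn(settings.chains)):
        init_rng = np.random.default_rng(child)
        walkers = _initial_walkers(
            init_rng, nwalkers, data, contrasts, prior_mean, log_prob
        )
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True, moves=_default_moves()
        )
        sampler._random = np.random.RandomState(
            child.generate_state(1, dtype=np.uint32)[0]
        )
        sampler.run_mcmc(walkers, total_steps, thin_by=thin, progress=False)
        flat = sampler.get_chain(discard=burn_steps).reshape(-1, ndim)
        chain_draws[chain] = flat[:retained]

    samples = PosteriorSamples(
        contrast_draws={
            a: chain_draws[:, :, 2 + n_sites + i] for i, a in enumerate(contrasts)
        },
        site_draws=chain_draws[:, :, 2 : 2 + n_sites],
        site_ids=sites,
        hyper_draws={
            "mu_site": chain_draws[:, :, 0],
            "tau_site": chain_draws[:, :, 1],
        },
        settings=settings,
    )

    if settings.chains >= 2:
        for a in contrasts:
            r = float(az.rhat(samples.contrast_draws[a]))
            if r > 1.01:
                msg = f"split R-hat {r:.4f} > 1.01 for contrast {a!r}: chains may not have converged"
                samples.warnings.append(msg)
                logger.warning(msg)
    return samples


# ---------------------------------------------------------------------------
# Convergence diagnostics


@dataclass
class ConvergenceReport:
    """Split R-hat and bulk effective sample size per monitored parameter."""

    rhat: dict[str, float | None]
    ess_bulk: dict[str, float]
    n_retained: int
    warnings: list[str] = field(default_factory=list)

    @property
    def max_rhat(self) -> float | None:
        vals = [v for v in self.rhat.values() if v is not None]
        return max(vals) if vals else None

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "n_retained": self.n_retained,
            "warnings": list(self.warnings),
        }


def _monitored(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    out = {f"log_rr_{a}": d for a, d in samples.contrast_draws.items()}
    for i, s in enumerate(samples.site_ids):
        out[f"alpha[{s}]"] = samples.site_draws[:, :, i]
    out.update(samples.hyper_draws)
    return out


def check_convergence(samples: PosteriorSamples) -> ConvergenceReport:
    """Split R-hat and ESS for every monitored parameter.

    With a single chain R-hat is unavailable and reported as None.
    """
    params = _monitored(samples)
    single = next(iter(params.values())).shape[0] < 2
    rhat: dict[str, float | None] = {}
    ess: dict[str, float] = {}
    warnings: list[str] = list(samples.warnings)
    if single:
        warnings.append("single chain: split R-hat unavailable")
    n_retained = samples.n_retained
    for name, draws in params.items():
        # the autocorrelation-based estimator can nominally exceed the draw
        # count on near-iid draws; the retained count is a hard ceiling
        ess[name] = min(float(az.ess(draws)), float(n_retained))
        rhat[name] = None if single else float(az.rhat(draws))
    report = ConvergenceReport(
        rhat=rhat, ess_bulk=ess, n_retained=samples.n_retained, warnings=warnings
    )
    bad = [k for k, v in rhat.items() if v is not None and v > 1.01]
    if bad:
        report.warnings.append(f"split R-hat > 1.01 for: {', '.join(sorted(bad))}")
    return report


def save_traceplots(samples: PosteriorSamples, outdir: str | Path) -> list[Path]:
    """Write one traceplot PNG per monitored parameter group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idata = samples.to_inference_data()
    paths = []
    for var in idata.posterior.data_vars:
        axes = az.plot_trace(idata, var_names=[var])
        fig = axes.ravel()[0].figure
        path = outdir / f"trace_{var}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
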