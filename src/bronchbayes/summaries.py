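"""Posterior reporting: medians, equi-tailed credible intervals, threshold probabilities.

A posterior (MCMC draws of log-RR, or a closed-form normal on log-RR) is
reduced to the quantities clinicians read: the median RR, the 95%
equi-tailed credible interval, and P(RR < t) for a decreasing ladder of
cutoffs t, each representing at least a (1 - t) x 100% relative reduction
in hospitalization risk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import PooledEvidence, apply_prior_weight
from .inference import (
    McmcSettings,
    NormalSummary,
    TrialDataset,
    fit_hierarchical_log_binomial,
)
from .priors import PriorSpec, ThresholdSet, prior_tail_probability, reference_priors

__all__ = [
    "PosteriorSummary",
    "summarize",
    "summarize_normal",
    "summarize_prior",
    "weight_sweep",
    "format_percent",
    "priors_table",
    "posterior_table",
]

MIN_DRAWS = 1000


@dataclass(frozen=True)
class PosteriorSummary:
    """Median RR, 95% equi-tailed CrI and threshold probabilities for one contrast."""

    contrast: str
    median_rr: float
    ci95: tuple[float, float]
    tail_probs: dict[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.median_rr <= hi:
            raise ValueError(
                f"median {self.median_rr} outside CrI ({lo}, {hi}) for {self.contrast}"
            )
        ts = sorted(self.tail_probs, reverse=True)
        probs = [self.tail_probs[t] for t in ts]
        if any(b > a + 1e-12 for a, b in zip(probs, probs[1:])):
            raise ValueError(f"tail probabilities not monotone in threshold: {self.tail_probs}")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "median_rr": self.median_rr,
            "ci95_lower": self.ci95[0],
            "ci95_upper": self.ci95[1],
            "tail_probs": {str(t): p for t, p in self.tail_probs.items()},
        }


def summarize(
    log_rr_draws: np.ndarray,
    thresholds: ThresholdSet = ThresholdSet(),
    contrast: str = "epidex",
) -> PosteriorSummary:
    """Summarize MCMC draws of a log-RR.

    Median and the 2.5%/97.5% quantiles use linear interpolation between
    order statistics; P(RR < t) is the fraction of draws below log t.
    """
    draws = np.asarray(log_rr_draws, float).reshape(-1)
    if draws.size < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} draws to summarize, got {draws.size}"
        )
    rr = np.exp(draws)
    lo, med, hi = np.quantile(rr, [0.025, 0.5, 0.975], method="linear")
    tails = {float(t): float(np.mean(rr < t)) for t in thresholds}
    return PosteriorSummary(
        contrast=contrast, median_rr=float(med), ci95=(float(lo), float(hi)),
        tail_probs=tails,
    )


def summarize_normal(
    ns: NormalSummary,
    thresholds: ThresholdSet = ThresholdSet(),
    contrast: str = "epidex",
) -> PosteriorSummary:
    """Closed-form twin of :func:`summarize` for a normal log-RR distribution."""
    z = stats.norm.ppf(0.975)
    med = math.exp(ns.mean_log_rr)
    ci = (
        math.exp(ns.mean_log_rr - z * ns.sd_log),
        math.exp(ns.mean_log_rr + z * ns.sd_log),
    )
    tails = {
        float(t): float(stats.norm.cdf((math.log(t) - ns.mean_log_rr) / ns.sd_log))
        for t in thresholds
    }
    return PosteriorSummary(contrast=contrast, median_rr=med, ci95=ci, tail_probs=tails)


def summarize_prior(
    prior: PriorSpec, thresholds: ThresholdSet = ThresholdSet()
) -> PosteriorSummary:
    """Prior viewed through the same reporting lens (median, CrI, tails)."""
    return summarize_normal(
        NormalSummary(mean_log_rr=prior.mean_log_rr, sd_log=prior.sd_log),
        thresholds,
        contrast=prior.label,
    )


def weight_sweep(
    data: TrialDataset,
    pooled: PooledEvidence,
    weights: Sequence[float],
    settings: McmcSettings = McmcSettings(),
    thresholds: ThresholdSet = ThresholdSet(),
    contrast: str = "epidex",
) -> list[tuple[float, PosteriorSummary]]:
    """Posterior summaries for a ladder of historical-evidence weights.

    Each weight w rescales the pooled prior SD by 1/sqrt(w) before fitting;
    w = 0 is the no-borrowing limit and substitutes the minimally
    informative prior.  Non-swept contrasts present in the data receive the
    minimally informative prior throughout, so the sweep isolates the effect
    of borrowing on the contrast of interest.
    """
    if len(weights) == 0:
        raise ValueError("weights must be non-empty")
    if any(w < 0 or w > 1 for w in weights):
        raise ValueError(f"weights must lie in [0, 1], got {list(weights)}")
    minimal = reference_priors()["minimally informative"]
    out = []
    for i, w in enumerate(weights):
        prior = minimal if w == 0 else apply_prior_weight(pooled, w)
        prior_map = {a: minimal for a in data.arms if a != "placebo"}
        prior_map[contrast] = prior
        chain_settings = McmcSettings(
            draws=settings.draws,
            burn_in=settings.burn_in,
            chains=settings.chains,
            seed=settings.seed + i,
        )
        fit = fit_hierarchical_log_binomial(data, prior_map, chain_settings)
        out.append((float(w), summarize(fit.log_rr(contrast), thresholds, contrast)))
    return out


# ---------------------------------------------------------------------------
# Report rendering


def format_percent(p: float) -> str:
    """Render a probability as integer percent, half away from zero.

    Values below 0.5% print as "≈ 0" and values at or above 99.5% as "100",
    matching the reporting convention for near-certain tails.
    """
    pct = 100.0 * p
    if pct < 0.5:
        return "≈ 0"
    return str(int(math.floor(pct + 0.5)))


def round_percent(p: float) -> int:
    """Integer percent, rounding half away from zero."""
    return int(math.floor(100.0 * p + 0.5))


def priors_table(
    priors: Sequence[PriorSpec],
    thresholds: ThresholdSet = ThresholdSet(),
    ess: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per prior: median RR, SD of log-RR, optional ESS, tail percents."""
    rows = []
    for p in priors:
        row: dict[str, object] = {
            "prior": p.label,
            "median_rr": p.median_rr,
            "sd_log": p.sd_log,
        }
        if ess is not None and p.label in ess:
            row["prior_ess"] = ess[p.label]
        for t in thresholds:
            row[f"P(RR<{t:g}) %"] = format_percent(prior_tail_probability(p, t))
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_table(
    summaries: Sequence[tuple[str, PosteriorSummary]],
    thresholds: ThresholdSet = ThresholdSet(),
) -> pd.DataFrame:
    """One row per (prior label, summary): median (95% CrI) and tail percents."""
    rows = []
    for label, s in summaries:
        row: dict[str, object] = {
            "prior": label,
            "contrast": s.contrast,
            "median_rr": round(s.median_rr, 2),
            "ci95": f"({s.ci95[0]:.2f}, {s.ci95[1]:.2f})",
        }
        for t in thresholds:
            row[f"P(RR<{t:g}) %"] = format_percent(s.tail_probs[float(t)])
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    payload: Mapping, path: str | Path, tables: Mapping[str, pd.DataFrame] | None = None
) -> None:
    """Write the machine-readable JSON report (and CSV tables alongside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if tables:
        for name, df in tables.items():
            df.to_csv(path.parent / f"{name}.csv", index=False)
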