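"""Archetype ("reference") priors on the relative risk of hospitalization.

A prior here is a lognormal distribution on the relative risk (RR),
parameterized by its median on the RR scale and the standard deviation of
log-RR.  Equivalently, log-RR ~ Normal(log(median_rr), sd_log**2).  Five
archetypes span the spectrum from minimally informative to strongly
skeptical; skeptics center their prior at RR = 1 (no effect) while
enthusiasts center it below 1, and the SD encodes how firmly the stance is
held.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "PriorSpec",
    "ThresholdSet",
    "ReferenceTrialInfo",
    "make_reference_prior",
    "prior_tail_probability",
    "prior_density_curve",
    "prior_ess",
    "reference_priors",
    "load_priors",
    "save_priors",
]

#: Default RR cutoffs reported throughout: a cutoff t corresponds to at
#: least a (1 - t) x 100% relative reduction in hospitalization risk.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.0, 0.9, 0.8, 0.6)


@dataclass(frozen=True)
class PriorSpec:
    """Lognormal prior on the RR: median ``median_rr``, SD of log-RR ``sd_log``."""

    label: str
    median_rr: float
    sd_log: float

    def __post_init__(self) -> None:
        if not (isinstance(self.median_rr, (int, float)) and self.median_rr > 0):
            raise ValueError(f"median_rr must be > 0, got {self.median_rr!r}")
        if not (isinstance(self.sd_log, (int, float)) and self.sd_log > 0):
            raise ValueError(f"sd_log must be > 0, got {self.sd_log!r}")

    @property
    def mean_log_rr(self) -> float:
        """Mean of the implied normal distribution on log-RR (= log median)."""
        return math.log(self.median_rr)


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly decreasing, positive RR cutoffs for tail-probability reports."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if len(ts) == 0:
            raise ValueError("thresholds must be non-empty")
        if any(t <= 0 for t in ts):
            raise ValueError(f"thresholds must all be > 0, got {ts}")
        if any(b >= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be strictly decreasing, got {ts}")
        object.__setattr__(self, "thresholds", ts)

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class ReferenceTrialInfo:
    """Size and log-RR standard error of the trial the prior is weighed against.

    Used to express a prior's information content as an equivalent number of
    trial participants: a prior exactly as informative as the trial's
    likelihood (sd_log == se_log_rr) is "worth" n_total participants.
    """

    n_total: int
    se_log_rr: float

    def __post_init__(self) -> None:
        if not self.n_total > 0:
            raise ValueError(f"n_total must be > 0, got {self.n_total!r}")
        if not self.se_log_rr > 0:
            raise ValueError(f"se_log_rr must be > 0, got {self.se_log_rr!r}")


def make_reference_prior(median_rr: float, sd_log: float, label: str) -> PriorSpec:
    """Validate and build a :class:`PriorSpec` from median RR and SD of log-RR."""
    return PriorSpec(label=label, median_rr=median_rr, sd_log=sd_log)


def prior_tail_probability(prior: PriorSpec, t: float) -> float:
    """P(RR < t) under the prior: Phi((ln t - ln median) / sd_log)."""
    if not t > 0:
        raise ValueError(f"threshold t must be > 0, got {t!r}")
    z = (math.log(t) - prior.mean_log_rr) / prior.sd_log
    return float(stats.norm.cdf(z))


def prior_density_curve(prior: PriorSpec, rr_grid: Sequence[float]) -> np.ndarray:
    """Lognormal density of the prior evaluated on a grid of RR values."""
    grid = np.asarray(rr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("rr_grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("rr_grid values must all be > 0")
    dist = stats.lognorm(s=prior.sd_log, scale=prior.median_rr)
    return dist.pdf(grid)


def _ess_variance_ratio(prior: PriorSpec, ref: ReferenceTrialInfo) -> float:
    # Information of the prior relative to the per-participant information
    # in the reference trial's likelihood.
    return ref.n_total * (ref.se_log_rr**2 / prior.sd_log**2)


def prior_ess(
    prior: PriorSpec,
    ref: ReferenceTrialInfo,
    formula: Callable[[PriorSpec, ReferenceTrialInfo], float] | None = None,
) -> float:
    """Equivalent prior sample size, in participants.

    Default formula: ``n_total * se_log_rr**2 / sd_log**2`` — the prior's
    precision expressed in units of the per-participant precision of the
    reference trial.  It is monotone decreasing in ``sd_log`` and equals
    ``n_total`` when the prior is exactly as informative as the trial.
    Alternative conventions can be supplied through ``formula``.
    """
    fn = formula if formula is not None else _ess_variance_ratio
    return float(fn(prior, ref))


#: The five archetype priors on the EpiDex relative risk, spanning
#: "no opinion" through strong skepticism.
_REFERENCE_TABLE: tuple[tuple[str, float, float], ...] = (
    ("minimally informative", 1.0, 10.0),
    ("strongly enthusiastic", 0.6, 0.31),
    ("moderately enthusiastic", 0.8, 0.14),
    ("moderately skeptical", 1.0, 0.31),
    ("strongly skeptical", 1.0, 0.14),
)


def reference_priors() -> dict[str, PriorSpec]:
    """The five archetype priors, keyed by label."""
    return {
        label: make_reference_prior(m, s, label) for label, m, s in _REFERENCE_TABLE
    }


# ---------------------------------------------------------------------------
# Priors file I/O: a flat list of {label, median_rr, sd_log} entries, or a
# mapping of contrast name -> such a list (one named set per treatment arm).


def _parse_prior_entry(entry: Mapping) -> PriorSpec:
    try:
        return make_reference_prior(
            float(entry["median_rr"]), float(entry["sd_log"]), str(entry["label"])
        )
    except KeyError as exc:
        raise ValueError(f"prior entry missing field {exc}: {dict(entry)!r}") from None


def load_priors(path: str | Path) -> dict[str, list[PriorSpec]] | list[PriorSpec]:
    """Read a YAML/JSON priors file.

    A list of entries yields ``list[PriorSpec]``; a mapping of contrast name
    to entry lists yields ``dict[str, list[PriorSpec]]``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, list):
        return [_parse_prior_entry(e) for e in data]
    if isinstance(data, dict):
        return {
            str(contrast): [_parse_prior_entry(e) for e in entries]
            for contrast, entries in data.items()
        }
    raise ValueError(f"priors file {path} must contain a list or mapping")


def save_priors(
    priors: Iterable[PriorSpec] | Mapping[str, Iterable[PriorSpec]],
    path: str | Path,
) -> None:
    """Write priors to YAML or JSON (by file suffix)."""

    def entries(ps: Iterable[PriorSpec]) -> list[dict]:
        return [
            {"label": p.label, "median_rr": p.median_rr, "sd_log": p.sd_log}
            for p in ps
        ]

    if isinstance(priors, Mapping):
        payload: object = {k: entries(v) for k, v in priors.items()}
    else:
        payload = entries(priors)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
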