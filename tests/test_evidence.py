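"""Historical-study effects, hierarchical pooling, and prior down-weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from bronchbayes import (
    McmcSettings,
    PooledEvidence,
    StudySummary,
    apply_prior_weight,
    pool_studies,
    read_studies_csv,
    simulate_study_collection,
    study_log_rr,
)

FAST_POOL = McmcSettings(draws=8000, burn_in=4000, chains=2, seed=5)


def test_study_log_rr_symmetric_counts():
    s = StudySummary("s", 10, 100, 10, 100)
    eff = study_log_rr(s)
    assert eff.mean_log_rr == pytest.approx(0.0)
    assert eff.sd_log == pytest.approx(math.sqrt(2 * (1 / 10 - 1 / 100)))
    assert not eff.continuity_corrected


def test_study_log_rr_trial_aggregate_counts():
    eff = study_log_rr(StudySummary("agg", 34, 199, 53, 200))
    assert eff.mean_log_rr == pytest.approx(-0.4389, abs=5e-5)
    assert eff.sd_log == pytest.approx(0.1956, abs=5e-5)


def test_study_log_rr_zero_cell_continuity_correction():
    eff = study_log_rr(StudySummary("z", 0, 50, 5, 50))
    assert np.isfinite(eff.mean_log_rr) and eff.sd_log > 0
    assert eff.continuity_corrected
    # matches the 0.5-corrected closed form
    a, n1, c, n0 = 0.5, 50.5, 5.5, 50.5
    assert eff.mean_log_rr == pytest.approx(math.log((a / n1) / (c / n0)))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(treated_events=1, treated_n=0, control_events=1, control_n=10),
        dict(treated_events=11, treated_n=10, control_events=1, control_n=10),
        dict(treated_events=-1, treated_n=10, control_events=1, control_n=10),
    ],
)
def test_study_summary_validation(kwargs):
    with pytest.raises(ValueError):
        StudySummary("bad", **kwargs)


def test_apply_prior_weight_matches_printed_progression():
    """Pooled sd 0.15 maps to 0.21 and 0.47 at weights 0.5 and 0.1."""
    pooled = PooledEvidence(mean_log_rr=math.log(0.89), sd_log=0.15, tau=0.1)
    full = apply_prior_weight(pooled, 1.0)
    assert full.sd_log == pytest.approx(0.15)
    assert full.median_rr == pytest.approx(0.89)
    half = apply_prior_weight(pooled, 0.5)
    assert half.sd_log == pytest.approx(0.2121, abs=5e-5)
    assert round(half.sd_log, 2) == 0.21
    tenth = apply_prior_weight(pooled, 0.1)
    assert tenth.sd_log == pytest.approx(0.4743, abs=5e-5)
    assert round(tenth.sd_log, 2) == 0.47
    # the median never moves with the weight
    assert half.median_rr == tenth.median_rr == full.median_rr


@hsettings(derandomize=True, max_examples=40, deadline=None)
@given(sd=st.floats(0.05, 1.0), w=st.floats(0.01, 1.0))
def test_weighting_scales_sd_exactly_inverse_root(sd, w):
    pooled = PooledEvidence(mean_log_rr=-0.1, sd_log=sd, tau=0.0)
    assert apply_prior_weight(pooled, w).sd_log == pytest.approx(sd / math.sqrt(w))


@pytest.mark.parametrize("w", [0.0, -0.1, 1.5])
def test_weight_domain(w):
    pooled = PooledEvidence(mean_log_rr=0.0, sd_log=0.2, tau=0.0)
    with pytest.raises(ValueError):
        apply_prior_weight(pooled, w)


def test_pool_requires_studies():
    with pytest.raises(ValueError):
        pool_studies([], FAST_POOL)


def test_pool_single_study_tracks_its_effect():
    s = StudySummary("only", 30, 150, 45, 150)
    eff = study_log_rr(s)
    pooled = pool_studies([s], FAST_POOL)
    assert pooled.mean_log_rr == pytest.approx(eff.mean_log_rr, abs=0.1)
    # between-study uncertainty can only widen the pooled sd
    assert pooled.sd_log >= 0.9 * eff.sd_log


def test_fixed_effect_closed_form_with_identical_studies():
    """With tau pinned at 0, k identical studies pool to se / sqrt(k)."""
    k = 4
    studies = [StudySummary(f"s{i}", 20, 100, 30, 100) for i in range(k)]
    se = study_log_rr(studies[0]).sd_log
    pooled = pool_studies(studies, fix_tau=0.0)
    # the vague mu hyperprior adds precision 1/100, so agreement is near-exact
    assert pooled.sd_log == pytest.approx(se / math.sqrt(k), rel=1e-3)
    assert pooled.mean_log_rr == pytest.approx(
        study_log_rr(studies[0]).mean_log_rr, abs=2e-4
    )


def test_mcmc_pooling_agrees_with_inverse_variance_oracle_when_tau_small():
    """Shrinking the heterogeneity prior recovers the fixed-effect answer."""
    studies = [
        StudySummary("a", 18, 90, 25, 92),
        StudySummary("b", 40, 210, 55, 200),
        StudySummary("c", 9, 60, 14, 61),
    ]
    y = np.array([study_log_rr(s).mean_log_rr for s in studies])
    v = np.array([study_log_rr(s).sd_log ** 2 for s in studies])
    w = 1 / v
    fe_mean = float((w * y).sum() / w.sum())
    fe_sd = float(1 / math.sqrt(w.sum()))
    pooled = pool_studies(studies, FAST_POOL, tau_prior_scale=1e-3)
    assert pooled.mean_log_rr == pytest.approx(fe_mean, abs=0.02)
    assert pooled.sd_log == pytest.approx(fe_sd, rel=0.15)


def test_pooling_matches_dersimonian_laird_on_heterogeneous_set():
    """Bayesian pooled mean lands near the DerSimonian-Laird point estimate."""
    studies = simulate_study_collection(
        k=12, true_mu_log_rr=math.log(0.8), tau=0.25, seed=42
    )
    effs = [study_log_rr(s) for s in studies]
    y = np.array([e.mean_log_rr for e in effs])
    v = np.array([e.sd_log ** 2 for e in effs])
    # DerSimonian-Laird moment estimator, written out as the oracle
    w = 1 / v
    fixed = (w * y).sum() / w.sum()
    q = float((w * (y - fixed) ** 2).sum())
    tau2 = max(0.0, (q - (len(y) - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    w_star = 1 / (v + tau2)
    dl_mean = float((w_star * y).sum() / w_star.sum())
    pooled = pool_studies(studies, FAST_POOL)
    assert pooled.mean_log_rr == pytest.approx(dl_mean, abs=0.06)


def test_heterogeneity_recovery():
    """Posterior median tau lands near the simulation truth at k = 20."""
    studies = simulate_study_collection(
        k=20, true_mu_log_rr=math.log(0.85), tau=0.3, per_arm_n_range=(150, 400),
        seed=7,
    )
    pooled = pool_studies(studies, McmcSettings(draws=12000, burn_in=6000, chains=2, seed=7))
    assert 0.15 <= pooled.tau <= 0.45


def test_pooling_is_reproducible():
    studies = [StudySummary("a", 18, 90, 25, 92), StudySummary("b", 40, 210, 55, 200)]
    p1 = pool_studies(studies, FAST_POOL)
    p2 = pool_studies(studies, FAST_POOL)
    assert p1 == p2


def test_read_studies_csv(tmp_path):
    path = tmp_path / "studies.csv"
    path.write_text(
        "study_id,treated_events,treated_n,control_events,control_n\n"
        "s1,10,100,15,100\ns2,5,50,9,55\n"
    )
    studies = read_studies_csv(path)
    assert [s.study_id for s in studies] == ["s1", "s2"]
    assert studies[1].control_n == 55


def test_read_studies_csv_reports_bad_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "study_id,treated_events,treated_n,control_events,control_n\n"
        "s1,10,100,15,100\ns2,60,50,9,55\n"
    )
    with pytest.raises(ValueError, match="row 1"):
        read_studies_csv(path)
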