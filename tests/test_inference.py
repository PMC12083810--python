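"""Trial data container, conjugate oracle, MCMC fit plumbing and diagnostics."""

import math

import numpy as np
import pytest

from bronchbayes import (
    McmcSettings,
    NormalSummary,
    PosteriorSamples,
    PriorSpec,
    TrialDataset,
    check_convergence,
    conjugate_posterior,
    fit_hierarchical_log_binomial,
    likelihood_summary,
    reference_priors,
    save_traceplots,
)

MINIMAL = PriorSpec("minimally informative", 1.0, 10.0)


# -- TrialDataset -----------------------------------------------------------


def test_dataset_round_trip_and_views(canbest, tmp_path):
    assert canbest.sites == ["pooled"]
    assert canbest.arms == ["placebo", "epi", "dex", "epidex"]
    totals = canbest.arm_totals()
    assert totals["n"].sum() == 797 and totals["events"].sum() == 185
    path = tmp_path / "trial.csv"
    canbest.to_csv(path)
    again = TrialDataset.from_csv(path)
    assert again.records.equals(canbest.records)


@pytest.mark.parametrize(
    "rows,msg",
    [
        ([("s1", "treatment", 10, 1)], "unknown arm"),
        ([("s1", "placebo", 10, 11)], "exceed"),
        ([("s1", "placebo", 10, 1), ("s1", "placebo", 10, 2)], "duplicate"),
        ([("s1", "epi", 10, 1)], "placebo"),
    ],
)
def test_dataset_validation(rows, msg):
    with pytest.raises(ValueError, match=msg):
        TrialDataset.from_records(rows)


def test_dataset_error_names_the_row():
    with pytest.raises(ValueError, match="row 1"):
        TrialDataset.from_records(
            [("s1", "placebo", 10, 1), ("s1", "epi", 10, 12)]
        )


def test_collapse_keeps_selected_arms(canbest):
    two = canbest.collapse(["placebo", "epidex"])
    assert two.arms == ["placebo", "epidex"]
    assert two.arm_totals()["n"].sum() == 399


# -- closed-form pieces -----------------------------------------------------


def test_likelihood_summary_aggregate_counts():
    lik = likelihood_summary(34, 199, 53, 200)
    assert lik.mean_log_rr == pytest.approx(-0.4389, abs=5e-5)
    assert lik.sd_log == pytest.approx(0.1956, abs=5e-5)


def test_likelihood_summary_equal_rates_is_null():
    assert likelihood_summary(20, 100, 20, 100).mean_log_rr == pytest.approx(0.0)


def test_likelihood_summary_zero_events_redirects():
    with pytest.raises(ValueError, match="continuity"):
        likelihood_summary(0, 100, 5, 100)


def test_conjugate_posterior_matches_hand_computation():
    prior = PriorSpec("strongly skeptical", 1.0, 0.14)
    lik = likelihood_summary(34, 199, 53, 200)
    post = conjugate_posterior(prior, lik)
    assert math.exp(post.mean_log_rr) == pytest.approx(0.862, abs=5e-4)
    # no-information limit: posterior reduces to the likelihood
    vague = conjugate_posterior(PriorSpec("v", 1.0, 1e6), lik)
    assert vague.mean_log_rr == pytest.approx(lik.mean_log_rr, abs=1e-6)
    assert vague.sd_log == pytest.approx(lik.sd_log, rel=1e-6)
    # equal precisions average the two means
    p = PriorSpec("e", 0.8, lik.sd_log)
    eq = conjugate_posterior(p, lik)
    assert eq.mean_log_rr == pytest.approx((math.log(0.8) + lik.mean_log_rr) / 2)


def test_mcmc_settings_validation():
    assert McmcSettings().retained == 10_000
    with pytest.raises(ValueError):
        McmcSettings(draws=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcSettings(chains=0)
    with pytest.raises(ValueError):
        NormalSummary(mean_log_rr=0.0, sd_log=0.0)


# -- MCMC fit ---------------------------------------------------------------


def test_fit_retains_exact_draw_count(canbest, fast_settings):
    fit = fit_hierarchical_log_binomial(
        canbest.collapse(["placebo", "epidex"]), {"epidex": MINIMAL}, fast_settings
    )
    assert fit.n_retained == fast_settings.chains * fast_settings.retained
    draws = fit.contrast_draws["epidex"]
    assert draws.shape == (fast_settings.chains, fast_settings.retained)
    assert np.all(np.isfinite(draws))
    # site risk stays below 1: alpha + beta < 0 for the fitted site
    assert np.all(fit.site_draws[:, :, 0] + draws < 0)


def test_fit_is_reproducible(canbest, fast_settings):
    args = (canbest, {a: MINIMAL for a in ("epi", "dex", "epidex")}, fast_settings)
    f1 = fit_hierarchical_log_binomial(*args)
    f2 = fit_hierarchical_log_binomial(*args)
    for arm in f1.contrast_draws:
        np.testing.assert_array_equal(f1.contrast_draws[arm], f2.contrast_draws[arm])
    np.testing.assert_array_equal(f1.site_draws, f2.site_draws)


def test_fit_requires_prior_per_contrast(canbest, fast_settings):
    with pytest.raises(ValueError, match="epidex"):
        fit_hierarchical_log_binomial(
            canbest, {"epi": MINIMAL, "dex": MINIMAL}, fast_settings
        )


def test_symmetric_arms_give_null_relative_risks(fast_settings):
    """Identical counts in every arm put all posterior medians near 1."""
    data = TrialDataset.from_records(
        [("s1", arm, 200, 50) for arm in ("placebo", "epi", "dex", "epidex")]
    )
    fit = fit_hierarchical_log_binomial(
        data, {a: MINIMAL for a in ("epi", "dex", "epidex")}, fast_settings
    )
    for arm in ("epi", "dex", "epidex"):
        rr = float(np.median(np.exp(fit.log_rr(arm))))
        assert 0.9 <= rr <= 1.1


# -- diagnostics ------------------------------------------------------------


def test_convergence_report_on_healthy_fit(canbest, fast_settings):
    fit = fit_hierarchical_log_binomial(
        canbest, {a: MINIMAL for a in ("epi", "dex", "epidex")}, fast_settings
    )
    report = check_convergence(fit)
    assert report.max_rhat is not None and report.max_rhat < 1.05
    assert set(report.rhat) >= {"log_rr_epidex", "mu_site", "tau_site"}
    # effective sample size cannot exceed the retained draw count
    assert all(0 < e <= report.n_retained for e in report.ess_bulk.values())


def _synthetic_samples(chain_means, n=1500, seed=0):
    rng = np.random.default_rng(seed)
    draws = np.stack([m + 0.05 * rng.standard_normal(n) for m in chain_means])
    return PosteriorSamples(
        contrast_draws={"epidex": draws},
        site_draws=draws[:, :, None],
        site_ids=["s1"],
        hyper_draws={"mu_site": draws.copy(), "tau_site": np.abs(draws) + 0.1},
        settings=McmcSettings(draws=2 * n, burn_in=n, chains=len(chain_means), seed=0),
    )


def test_rhat_flags_disjoint_chains():
    """Chains stuck in separated regions must produce a large R-hat."""
    report = check_convergence(_synthetic_samples([0.0, 5.0]))
    assert report.rhat["log_rr_epidex"] > 1.1
    assert any("R-hat" in w for w in report.warnings)


def test_single_chain_has_no_rhat():
    report = check_convergence(_synthetic_samples([0.0]))
    assert report.rhat["log_rr_epidex"] is None
    assert any("single chain" in w for w in report.warnings)


def test_traceplot_export(canbest, fast_settings, tmp_path):
    fit = fit_hierarchical_log_binomial(
        canbest.collapse(["placebo", "epidex"]), {"epidex": MINIMAL}, fast_settings
    )
    paths = save_traceplots(fit, tmp_path)
    assert paths and all(p.exists() and p.suffix == ".png" for p in paths)
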