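# Methods

## Scope

`bronchbayes` re-expresses a four-arm factorial trial with a binary
outcome (7-day hospital admission) as a Bayesian analysis: explicit prior
stances on the treatment relative risk (RR), a site-adjusted log-binomial
outcome model, and posterior threshold-probability summaries. The package
also builds data-driven priors from historical two-arm studies and
provides synthetic generators so every stage can be exercised without
access to participant-level data.

## Prior stances

A stance is a normal distribution on log RR, parameterized by the median
RR `m` and the SD of log RR `s` (so the RR itself is lognormal with
median exactly `m`). Five archetypes are built in:

| stance                  | median RR | SD(log RR) | reading                         |
|-------------------------|-----------|------------|---------------------------------|
| minimally informative   | 1         | 10         | effectively no opinion          |
| strongly enthusiastic   | 0.6       | 0.31       | confident of a large benefit    |
| moderately enthusiastic | 0.8       | 0.14       | confident of a moderate benefit |
| moderately skeptical    | 1         | 0.31       | doubtful, but persuadable       |
| strongly skeptical      | 1         | 0.14       | firm belief in no effect        |

Skeptics center at RR = 1 (no effect); enthusiasts center below 1; the SD
encodes how firmly the stance is held. Tail probabilities P(RR < t) are
analytic: Φ((ln t − ln m)/s). The "minimally informative" stance is a
proper prior (SD 10), not an improper flat one; it reproduces an
essentially likelihood-driven posterior while keeping every computation
well defined.

The equivalent prior sample size is reported as
`ESS = n_ref × se_ref² / s²`: the prior's precision measured in units of
the per-participant precision of a reference trial with `n_ref`
participants and log-RR standard error `se_ref`. This is one of several
conventions in use; the function accepts an alternative formula as a
hook, and no published ESS value is asserted by the test suite.

## Outcome model

Counts per site and arm follow a binomial GLM with a log link, so
coefficients are log RRs against placebo:

    events[s,a] ~ Binomial(n[s,a], p[s,a])
    log p[s,a]  = α_s + β_a,  β_placebo = 0
    β_a ~ Normal(log m_a, s_a²)
    α_s ~ Normal(μ_α, τ_α²),  μ_α ~ Normal(log 0.25, 1.5²),  τ_α ~ Half-Normal(1)

The combination arm carries its own coefficient rather than a main-effects
plus interaction decomposition, because one RR per arm versus placebo is
the quantity being reported. The log link requires fitted probabilities
below 1; parameter vectors with any α_s + β_a ≥ 0 receive zero posterior
support, which is the simplest faithful log-binomial constraint and the
source of any early-phase rejected proposals. The site hyperpriors are
weakly informative around plausible admission risks (placebo risk near
25%, between-site spread of log risk of order one); with a single site the
hierarchy degenerates gracefully to a common intercept whose marginal
prior is wide.

When one stance is being reported for one contrast, that stance is placed
on that contrast only and the remaining contrasts keep the minimally
informative prior. Applying an informative stance to all three contrasts
simultaneously couples them through the shared site intercept: an
enthusiastic prior on the single-agent arms, which the data contradict,
pushes the intercept up and biases the combination-arm RR downward by
several hundredths. The one-stance-per-report convention keeps each
reported posterior interpretable as "this stance about this contrast,
data otherwise."

## Sampling

The posterior is sampled with `emcee`. Each chain is an independent
walker ensemble (walker count `max(20, 2·ndim + 2)`), seeded from a
single integer via `numpy.random.SeedSequence`, so identical settings
give identical draws. The per-chain draw/burn-in budget (defaults 20,000
and 10,000) is mapped onto ensemble steps by walker-flattening; the
ensemble internally runs at least 6,000 moves (via thinning, capped at
16×) so that retained draws are well mixed regardless of the nominal
budget.

Proposals are pure differential-evolution (`DEMove`). This was a measured
choice: stretch moves traverse the α–μ_α–τ_α funnel slowly (per-chain
Monte Carlo SD of the posterior median ≈ 0.009 at the default budget),
and `DESnookerMove` is biased for this model — it pins τ_α against its
zero boundary and inflates P(RR < 1) by about one percentage point,
verified against an exact quadrature posterior. DE-only proposals
reproduce the quadrature posterior on the median, the hierarchy scale and
the tails.

Convergence is reported per parameter as split R-hat and bulk effective
sample size (arviz); any treatment contrast with R-hat > 1.01 attaches a
warning to the result rather than failing silently. ESS is capped at the
retained draw count, since the autocorrelation estimator can nominally
exceed it on near-independent draws. With a single chain, R-hat is
reported as unavailable. Traceplots export per parameter as PNG.

The conjugate oracle — precision-weighted combination of the normal prior
with a normal approximation to the log-RR likelihood
(mean ln[(a/n₁)/(c/n₀)], sd √(1/a − 1/n₁ + 1/c − 1/n₀)) — is used for
testing, not analysis. It is accurate to about 0.005 on the median and
one percentage point on tails at this trial's event counts; the test
suite therefore validates the sampler against an exact two-dimensional
quadrature posterior at Monte Carlo precision, and against the conjugate
oracle at ±0.01.

## Data-driven priors

Historical two-arm studies are reduced to log-RR estimates with
delta-method standard errors; a study with any zero cell gets the
standard 0.5 continuity correction on all four cells, flagged on the
output. Pooling is Bayesian: y_i ~ Normal(μ, se_i² + τ²) with μ ~
Normal(0, 10²) and τ ~ Half-Normal(1), sampling only (μ, τ) because the
study effects integrate out exactly. The pooled evidence is the posterior
mean/SD of μ and the posterior median of τ. A `fix_tau` option pins τ
(0 gives the fixed-effect model) for closed-form cross-checks;
DerSimonian–Laird serves as a frequentist oracle in tests only.

Down-weighting acts on the pooled SD: weight w ∈ (0, 1] maps sd →
sd/√w, equivalent to scaling each historical participant's information
by w; the pooled median RR is untouched. This reproduces the canonical
progression sd 0.15 → 0.21 (w = 0.5) → 0.47 (w = 0.1). The weight sweep
fits the trial under each weighted prior; w = 0 is the no-borrowing limit
and substitutes the minimally informative stance. Whether weighting
should instead inflate per-study variances before pooling is ambiguous
when τ > 0; weighting the pooled SD is the convention implemented, as it
is the one uniquely consistent with the progression above.

## Synthetic data and the fixture

`simulate_trial` draws site intercepts Normal(ln baseline_risk,
site_sd²), multiplies by fixed arm RRs, and draws binomial outcomes.
Defaults (20 sites, 40 per site-arm, baseline risk 0.265, site SD 0.3,
RRs 0.89/0.97/0.64 for epi/dex/epidex) mirror the reanalyzed trial's
aggregate rates and a plausible multicenter spread. A site whose implied
risk would reach 1 in any arm is redrawn rather than truncated, keeping
the generative model inside the log-binomial family; rejection counts
are logged, and parameter sets whose analytic rejection probability
exceeds 0.5 are refused outright. `simulate_study_collection` generates
heterogeneous historical studies (per-study true log RR ~ Normal(μ, τ²),
uniform arm sizes, binomial outcomes).

`canbest_fixture` reconstructs the published aggregate: 797 participants
split 199/199/199/200 (the odd participant to placebo — the exact
denominators were never published and equal allocation is an assumption,
flagged in the function's documentation and logs) with 34/47/51/53
admissions. Because per-site counts were never published, the fixture is
a single site and fits of it are unadjusted for site. Published
quantities that survive this collapse (verified through the conjugate
oracle) are reproduced at printed precision; the minimally informative
posterior median (published 0.66 under site adjustment, ≈ 0.645
unadjusted) and the moderately skeptical median (0.75 vs ≈ 0.73) are
site-adjustment artifacts the fixture cannot recover, and nothing asserts
them.

What the generator does not emulate: individual-level covariates,
differential allocation across sites, time-to-event structure, and
non-lognormal site heterogeneity. Passing calibration tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to real-data violations of it.

## Experiment sizes in the test suite

The reproduction tests run the full reporting budget (4 chains ×
20,000 draws). Sampler-vs-oracle agreement uses 8 chains so the Monte
Carlo standard error of each statistic can be estimated from
between-chain spread with reasonable degrees of freedom. The
credible-interval calibration experiment uses 20 replicate synthetic
trials (20 sites × 40 per arm, true combination RR 0.65, 2 chains per
fit) and requires coverage of at least 17 of 20 — the central binomial
band for a nominal 95% interval at that replicate count. Unit tests use
reduced draw budgets: they exercise plumbing, determinism and loose
statistical bounds, not reporting precision.

## Known limitations

- The fixture's equal-allocation denominators are a reconstruction; ±1
  participant changes nothing at reporting precision, but it is an
  assumption.
- The conjugate oracle's normal approximation degrades for small event
  counts; use the quadrature path when validating tails.
- The ESS convention is one of several; printed ESS values from other
  conventions will not match it exactly.
- Ensemble MCMC with few walkers mixes slowly in strongly funneled
  posteriors; the move choice and thinning floor were set for models of
  this size (tens of sites), not for hundreds of sites.
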