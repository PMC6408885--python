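# Methods

This note documents the statistical procedures the package implements, the
assumptions and defaults of its synthetic-data generators, the numerical
choices inside the fitters, and what the test suite does and does not
establish about real field data.

## 1. Event data and aggregation

The atomic inputs are timestamped feeder-visit events (site, time, PIT-tag
id, species) and call-annotation events (site, time, call type, note count).
Timestamps are local clock time at 1-second resolution; no DST arithmetic is
performed (trials span hours, never a clock change). An empty tag id denotes
an untagged visitor: the RFID system reads only ringed birds, so untagged
visits count toward visit totals but can never contribute to
unique-individual counts.

Hourly aggregation uses left-closed clock-hour bins [h:00, h+1:00), one row
per daylight hour per site, so every event lands in exactly one bin. The
calls-per-visit rate for an hour is the pooled ratio n_calls/n_visits, not a
mean of per-visit counts; the two coincide when every visit is observed, and
the pooled form is well defined for the call-annotation stream, which does
not link calls to visits. Hours with zero visits have an *undefined* rate
(NaN) and are excluded from the permutation dataset — a ratio with a zero
denominator is not a zero observation. Morning means strictly before 12:00;
12:00 itself is afternoon.

Playback trials derive three responses from the raw visit log: latency from
trial onset to first recorded visit, censored by entry at exactly 60 min when
no visit falls inside the one-hour analysis window (the window is
closed-left, open-right); initial recruitment = distinct tagged birds in the
closed 2-minute window after discovery; and total birds = distinct tagged
birds over [start, start+60 min). Initial recruitment is undefined without a
discovery; both counts are therefore treated as missing for censored trials
and dropped listwise from the count models, while the latency model keeps all
trials with the censored value 60. The 60-vs-120-minute question (feeders
stayed deployed for 2 h) is resolved in favour of the one-hour analysis
window: discoveries after 60 min are censored, not excluded.

## 2. The restricted permutation test

The headline statistic is mean(calls-per-visit over afternoon hour rows) −
mean(over morning rows), pooling rows across trials with equal weight. The
null distribution shuffles the *hour* column within each trial block,
leaving every other column fixed; each trial's multiset of hour labels is
preserved exactly, so the test conditions on each trial's sampling pattern
and only asks whether the rate is exchangeable across hours within a trial.
Because the statistic depends on hours only through the AM/PM split, each
replicate reduces to drawing which rows of a trial receive its morning
labels; the implementation vectorises this over replicates from one seeded
generator (a pure function of data, replicate count and seed).

Two p-values are reported. The primary estimate is the two-sided add-one
p = (1 + #{|null| ≥ |observed|}) / (1 + n_perm), matching the study
convention that all tests are two-tailed. The literal one-sided count in the
observed direction is reported alongside, because the test's original verbal
description is one-sided; publishing both exposes the discrepancy instead of
silently resolving it. Numerical ties (null replicates equal to the observed
value up to floating-point path differences) count as at-least-as-extreme.
The 95% null range uses linear-interpolation percentiles (2.5th and 97.5th).

At the nominal 0.05 level the add-one estimator with 2,000 permutations
rejects with probability 100/2001 ≈ 0.04998 under exchangeability; the
calibration study in the acceptance script measures this empirically over
500 replicate experiments.

## 3. Random-intercept GLMMs

Each playback response is modelled with fixed effects time-of-day (PM vs AM
reference), treatment (playback vs control reference), trial order (numeric
1–4, a single degree of freedom), optionally the time-of-day × treatment
interaction, and a Gaussian random intercept per site. Latency uses a Gamma
family with log link and a free shape k; the counts use Poisson with log
link. Entering order as numeric (not ordinal factor) matches its single
degree of freedom in the target analysis.

The marginal likelihood integrates the site intercept by adaptive
Gauss–Hermite quadrature: per site, the conditional mode of the integrand is
found by a damped 1-D Newton iteration, the curvature there sets the scaling,
and the rule's nodes are recentred and rescaled before summation (one node
recovers the Laplace approximation). The outer optimisation is L-BFGS-B over
(coefficients, log σ, log k), started from the ordinary GLM fit, with
Fisher-identity gradients — posterior-weighted score sums over the quadrature
nodes, which match the gradient of the exact marginal likelihood to the
(negligible, at the default 15 nodes) quadrature error. With fewer than 5
nodes the optimiser switches to finite-difference gradients of the objective
itself, since the Fisher identity is no longer accurate there. Convergence
requires the optimiser's own criterion (relative objective change below
1e-12) or a gradient norm below 1e-3; anything else flags the result, never
silently. Standard errors come from inverting the numerical observed
information of the marginal deviance at the optimum; Wald z and two-tailed
normal p-values follow, with no degrees-of-freedom correction.

Pinning the random-intercept variance to zero collapses the marginal
likelihood to the ordinary GLM likelihood, which the package then solves
exactly: IRLS/Newton for Poisson, Fisher scoring for Gamma (whose expected
information is constant in the coefficients, making the iteration globally
stable; the Gamma shape factors out of the coefficient score and is estimated
afterwards by solving its profile score with Brent's method). The test suite
checks this pinned path against an independent IRLS implementation
(statsmodels GLM) to 1e-6 relative tolerance — the mixed fitter itself never
delegates to a mixed-model package.

The interaction rule fits the full model first and drops the interaction
when its Wald p ≥ 0.05 (a p exactly at the threshold drops it), refitting the
reduced model; both fits are retained in the report. Species-level analyses
rerun the identical pipeline on per-species response derivations; sparse
subsets are flagged with a warning but still fitted, and empty ones skipped.

Censored latencies enter the Gamma likelihood as the value 60 — faithful to
the analysis being re-implemented, and a known source of (small) attenuation
when censoring occurs; a proper censored likelihood would be the natural
extension but is deliberately not the default, since the point of the package
is the original procedure.

## 4. Synthetic-data generators

The generators encode the study conditions so every downstream stage is
testable without the undeposited field data. All outputs are pure functions
of (configuration, seed).

**Population.** Default 1,000 birds; species composition (0.501, 0.360,
0.139) — the two larger shares follow the reported across-site means (50.1%
great, 36.0% blue tits) and the scarcest species closes the simplex, since
the three reported means sum to 100.1% and cannot be used verbatim as a
composition. 75% of birds carry tags (reported range: 70–80%); untagged birds
appear in event streams with an empty tag id and species UNKNOWN, mirroring
the field system's blindness. 80% of birds use a single home site (reported:
nearly 80% of individuals detected at only one site); the rest use two.

**Discovery trials (default 18, one site/day each).** The first-visit time
after sunrise is lognormal with median 27 min and log-sd 1.25, chosen so the
quartile ratio exp(0.6745·1.25) ≈ 2.32 brackets the reported quartile ratios
(27/13.5 = 2.0 below, 60.8/27 = 2.25 above); draws beyond sunset are
resampled. Subsequent visits follow an inhomogeneous Poisson process by
thinning under a tent intensity: zero at sunrise (07:00 default), the
configured peak rate (15 visits/h) at 13:00, zero at sunset (17:45) — the
simplest shape matching a morning rise and evening decline. Each visit emits
Poisson-many calls with log-rate linear in clock hour. The slope is
calibrated by solving, at hour-bin centres, for the value making the
afternoon-minus-morning mean rate equal the configured target (−0.24
calls/visit at a mid-day base rate of 0.5); a zero target yields an exactly
flat profile, which is what the type-I-error study relies on. Because real
visits cluster toward the intensity peak within each hour and low-traffic
hours drop out of the dataset, the *realised* statistic is mildly attenuated
relative to the bin-centre target: at defaults the observed mean difference
is ≈ −0.22 rather than −0.24. The calibration is documented as approximate;
the null case is exact. Note counts per call are 1 + Poisson(mean − 1)
(default mean 3.1, hence variance 2.1 — the field s.d. of 1.3 is not
moment-matched, only the mean matters to any downstream quantity). Call types
follow the caller's species (chirps for blue/great tits, dä/D for marsh
tits); unidentified callers draw a type at the population's chirp share.

**Playback experiments (default 12 sites × 4 conditions).** Trials start
08:30 (AM) or 14:30 (PM), five days apart per site, in a random order 1–4.
Latency is Gamma on the log-link linear predictor; the configured slopes
(time-of-day 1.03, treatment −1.17, order −0.59) are the reported effect
magnitudes, while the intercept default 3.0 (log-minutes) is a generator
choice placing control-morning latencies at a few minutes, as observed. (The
original analysis fitted its latency model on an inverse-link scale, so its
intercept is not transferable to a log-scale generator; equivalence is
qualitative by design.) The Gamma shape default 2.5 is a free parameter set
for realistic skew. Counts: unique tagged visitors in the 2-min window are
Poisson with the reported coefficients (intercept 1.25, slopes −0.09, 0.52,
0.31), floored at 1 because the discoverer is always counted; additional
unique visitors arrive in (discovery+2 min, 60 min) as an independent
Poisson with rate μ_total − μ_recruit, so the 60-min count is Poisson with
mean μ_total by superposition. The total-birds intercept defaults to 1.70
rather than the reported 1.16: the two reported count intercepts with
near-identical slopes would make the 60-min pool *smaller* than its 2-min
subset, which no generative process can realise; 1.70 preserves the reported
slopes and the containment. The two count responses share one site intercept
(s.d. 0.3, a free parameter — no variance components are reported) so the
implied extra-arrival rate stays positive; latency has its own. Drawn
latencies are floored at 1 s (log resolution). Untagged visitors and repeat
visits are sprinkled after discovery for realism; neither affects any
response measure.

**Stimuli.** Each stimulus is 4 calls per species (12 slots) in seeded random
order at sorted-uniform offsets across a 10-min window, scheduled at trial
start and +60 min; note counts use the same 1 + Poisson(2.1) law.

What the generators deliberately do not emulate: predator events, weather,
dominance structure, within-day movement beyond the one-or-two-home-sites
flag, species differences in detectability, audio properties of calls, and
logging failures (missing counts arise only from undiscovered feeders).
Passing tests therefore show that the *procedures* are correct and
well-calibrated under the stated generative assumptions — not that the
field system satisfies those assumptions.

## 5. The cost–benefit model

The verbal recruitment-calling framework specifies only orderings (call when
alone or in a small group, not in a large one), so the functional forms are
package choices constrained by those orderings, each swappable via strategy
hooks: dilution benefit 1/(N(N+1)) (the exact drop in per-capita risk from
one recruit under equal risk sharing); attraction probability
1 − (1−q)^(N_pop−N) (independent listeners, detection probability q = 0.1
default); competition cost (1−s)·N/(N+1) (zero for fully shareable food,
saturating at 1−s; default shareability 0.5); conspicuousness cost
h₀·(c−1)·N/N_pop (baseline hazard h₀ = 0.1, calling doubles detectability,
c = 2, scaled by the fraction of the population concentrated at the patch).
Weights (w_b, w_c, w_p) = (1, 0.05, 0.2) were calibrated once so the three
qualitative regimes land at N = 1 (clear call), N ≈ 5 (near the cost=benefit
boundary) and N ≥ 20 (clear no-call) for N_pop = 50; the calibration check
prints from `analysis/05_recruitment_economics.py`. Regimes are ALONE
(N = 1), SMALL_GROUP (net ≥ −0.02, the documented boundary band) and
LARGE_GROUP below it. Net benefit is strictly decreasing in N at the
defaults, so the CALL region is a prefix of group sizes with a single
switch; shrinking the listener pool (the afternoon analogue) lowers the net
benefit at every group size. All numeric outputs of this module illustrate
the framework's logic; none are field estimates.

## 6. Problem sizes and numerical tolerances

The repeated-simulation studies use the study's own dimensions — 18
discovery trials, 12-site playback experiments — with 500 replicates for the
permutation-test calibration (2,000 permutations each) and 200 replicates
for parameter recovery; these sizes put Monte Carlo standard errors well
below the effects being checked while keeping each study in the minutes
range. Optimiser tolerances: GLM Newton/Fisher steps to 1e-12; L-BFGS-B
ftol 1e-12 / gtol 1e-8; site-mode Newton to 1e-12 with steps clipped to ±2;
quadrature default 15 nodes (1 and 25 agree to ~5e-4 on the example fits).
Percentile definition: linear interpolation. Permutation tie tolerance:
1e-9 relative. Degenerate inputs are errors, not guesses: statistics with an
empty morning or afternoon, recruitment of a censored trial, designs with a
single-level factor, scenarios with N > N_pop.

## 7. Known limitations

* Censored-as-60 latency entry (faithful to the original analysis) slightly
  attenuates the latency model when censoring occurs; the recovery study
  shows all slope estimates unbiased within Monte Carlo error, with a small
  deterministic offset confined to the latency intercept (≈ −0.05 on 3.0).
* The calls-per-visit generator calibrates at hour-bin centres; the realised
  afternoon−morning difference is attenuated ~8% at the defaults (see the
  generator section above).
* The permutation test's vectorised null uses one seeded stream rather than
  per-replicate substreams; results are reproducible given (data, n_perm,
  seed) but not invariant to changing n_perm.
* The GLMM supports exactly one Gaussian random intercept (the design's site
  effect); crossed or nested random effects are out of scope, as are
  families beyond Gamma/Poisson log-link.
* Species-level playback analyses re-derive responses per species from the
  same event streams; with the default composition the marsh-tit subset is
  sparse and its estimates unstable, which the pipeline flags rather than
  hides.
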