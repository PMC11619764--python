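# Methods

`bvitals` implements a passive-sensing pipeline for repeatedly measured
depressive symptoms: daily behavioral features are extracted from four
smartphone event streams, summarized into weekly features aligned with
biweekly PHQ-8 assessments, decomposed into a person's global level and
weekly deviations from it, and related to symptoms with linear
mixed-effects models that separate between-person from within-person
association. Because raw cohort data of this kind are not publicly
deposited, the package ships a first-class synthetic cohort generator and
validates the whole pipeline against it.

## Daily features

Events are half-open intervals `[start, end)` in participant-local clock
time; days run midnight to midnight (a travel day may pass an explicit
elapsed window, which becomes the coverage denominator). Per
participant-day we compute:

- **Sleep proxies** from the display stream. The main rest window is the
  longest display-off/uncovered gap starting between 19:00 (previous day)
  and 04:00 and ending between 03:00 and 14:00, at least 3 h long.
  Display-on episodes of ≤ 20 min inside a gap are bridged; bridged
  episodes of ≥ 2 min count as sleep interruptions. Bedtime
  (`sleep_start`), wake-up time, time in bed (= wake − bedtime mod 24)
  and the interruption count follow. All thresholds are configurable
  (`SleepParams`); the defaults follow the screen-based sleep-inference
  literature. `sleep_start` is stored on an unwrapped "hours since the
  previous midnight" axis (23.0 = 11 pm, 25.5 = 1:30 am) so that
  variability statistics are not corrupted by the midnight wrap-around.
- **Activity**: total daily step count (per 1000) from pedometer events,
  and walking rate = steps inside `walking` activity bouts divided by
  summed bout seconds. With no walking bouts the rate is unavailable
  (NaN), never imputed.
- **Social engagement / mobility** from cluster-labelled location visits:
  the dwell-time profile over visited clusters gives the normalized
  location entropy −Σ pₖ ln pₖ / ln K ∈ [0, 1] (defined as 0 for K = 1;
  the normalization makes the log base irrelevant), hours at home,
  log(1 + K) clusters, and log(1 + D) where D is the dwell-weighted mean
  distance from home over non-home clusters. The `log1p` form handles
  at-home-all-day zeros. Home is the cluster with the largest cumulative
  00:00–06:00 dwell across the observation window, ties to the smallest
  id.
- **Coverage**: per stream, merged event duration divided by the elapsed
  day, capped at 1; overall coverage is the mean of the four streams. A
  day is valid when overall coverage exceeds a configurable threshold
  (default 0) and at least one feature is computable.

## Weekly aggregation and centering

For a PHQ-8 at time `t`, the weekly summary `X_it` is the mean or SD
(n−1 denominator) of a daily feature over `[date(t) − 7 days, t)` —
seven full days plus the partial PHQ-8 day. A summary is valid with ≥ 5
contributing days; day counts are feature-specific because stream
outages hit features unevenly. The 18 selected summaries are the means
and SDs of bedtime, wake time and time in bed; mean interruptions; means
and SDs of step count and walking rate; mean entropy; and means and SDs
of log clusters, time at home and log distance.

The global feature `X̄_i` is the unweighted mean of a participant's
valid weekly values; the deviation is `ΔX_it = X_it − X̄_i`. Deviations
sum to zero per participant by construction; `X̄` indexes *who* tends to
be symptomatic, `ΔX` *when*. Participants with no valid weeks for a
feature drop out of that feature's model only. Global features across
participants are screened with Spearman correlations; pairs with
|r| ≥ 0.70 are flagged.

## Mixed model

For each summary feature we fit, by REML (statsmodels `MixedLM`,
L-BFGS, fixed settings),

    PHQ_it = β0 + βB·X̄_i + βW·ΔX_it + γ·c_it + b0_i + b1_i·√t + ε_it

with covariates `c_it` = age, gender (reference male-or-other),
occupation (reference not-employed), living status (reference
with-others), treatment arm (reference control), √week and
treatment×√week; random intercept and slope on √t with unstructured 2×2
covariance; `ε ~ N(0, σ²)`. The √week transform matches the initially
steeper symptom decline; the random slope uses the same transform.
CIs are Wald (±1.96 SE); the baseline (week-0) PHQ-8 is not modelled.

Boundary handling: the no-random-effects stratum is part of the REML
parameter space, so after the full fit we evaluate the restricted
likelihood with the covariance at (a 1e-8 ridge of) zero; if that is at
least as high, the optimizer stopped on a flat ridge and the model is
reduced — exactly — to OLS. A singular slope variance triggers a refit
with random intercept only, flagged in the output. Non-convergence after
reduction yields a flagged OLS row so the screen can continue.

Fit indices: marginal R² = var(Xβ̂) / (var(Xβ̂) + mean_i zᵢ'Ĝzᵢ + σ̂²)
(Nakagawa–Schielzeth with the random-slope extension), and
ΔR² = marginal R²(full) − marginal R²(covariate-only) on the identical
rows; ΔR² may be slightly negative in finite samples and is reported to
3 decimals (estimates and CIs to 2).

## Synthetic cohort generator

Defaults emulate the study conditions: 131 outpatients, 16 weeks, up to
8 biweekly PHQ-8 waves (weeks 2–16 at 18:00), four concurrent event
streams whose per-stream daily coverage is Beta(75, 0.8) (median ≈ 0.99),
and day-/wave-level missingness both 0 by default (the emulated cohort
was near-complete); both are configurable, missingness is completely at
random unless the informative-missingness switch is enabled. Time is
participant-local; no time-zone travel by default.

Person-level traits: demographics match the emulated cohort's margins
(age ~ N(32.8, 11.3²) truncated to 18–70, 73.3% female, 85.5% employed,
16.8% living alone, 1:1 treatment allocation). Behavioral set points:
wake time N(7.5, 1.0²) h, wake-time day-to-day SD lognormal (median
0.8 h), bedtime N(23.4, 1.0²) on the unwrapped axis with SD lognormal
(median 0.6 h), interruption rate Gamma(2, 0.5)/day, daily steps
lognormal (median 7000, capped 1500–20000) with person CV ~ N(0.35,
0.10²), walking rate N(1.5, 0.25²) steps/s, away-cluster count
N(3, 1²), home dwell fraction N(0.65, 0.12²) truncated to ≥ 0.35 so the
home cluster dominates the night, Dirichlet evenness N(1.2, 0.4²) for
away time, distances lognormal around a person median of 2 km.

Daily values are drawn around the set points. The location dwell
profile is simulated first and the mobility features are deterministic
functions of it, so jointly infeasible feature combinations cannot
arise. Daily steps are floored at 100 (so walking bouts always exist
and walking rate is defined) and capped so the bouts fit between wake
and 23:00; interruption counts are capped to what the rendered night can
hold. These guards affect far tails only.

The renderer lays events out so extraction inverts generation: pedometer
bouts carry integer steps summing exactly to the daily total (largest
remainder apportionment) and coincide with `walking` activity bouts, so
the rate is recovered exactly; zero-step and `stationary` filler events
plus a nighttime "coverage hole" reproduce the drawn coverage without
touching any feature; location visits tile the day with exact dwell
hours; the display timeline alternates on-blocks ≥ 27 min (never
bridgeable) with short off-blocks during waking time and encodes each
night as an off period with 5-min interruption episodes. Since a night
belongs to the morning's day, the renderer needs the adjacent bedtime:
it accepts one-or-many consecutive daily records and synthesizes a
previous evening for the first one.

PHQ-8 is drawn from the same between/within model the analysis fits
(defaults: β0 = 9.5; βB = 1.5 PHQ points per hour of global wake-time
SD; βW = −0.16 per 1000 steps of weekly step-count deviation; γ for age
0.03, female 0.5, employed −0.8, alone 0.6, √week −0.9,
treatment×√week −0.35; random-effect covariance [[9, −0.4], [−0.4,
0.16]]; residual SD 2.5), then rounded and clamped to [0, 24].
Generation-side weekly/global/deviation triples are computed from the
complete true daily features — symptoms do not depend on whether the
phone was observed — and missingness is applied to the observed copies
afterwards.

## What passing tests do and do not show

The generator reproduces the marginal structure of a passive-sensing
cohort (set-point heterogeneity, daily noise, near-complete coverage,
integer floor/ceiling PHQ) but not autocorrelated behavior, seasonality,
measurement drift, informative missingness (off by default) or
time-zone travel. Round-trip and recovery results therefore validate
the pipeline's bookkeeping and estimation machinery, not the clinical
validity of the features on real data.

Known statistical limitations, measured on this generator: the PHQ
floor/ceiling makes the linear model mildly misspecified at the
extremes; and the plug-in REML Wald test for the *between* coefficient
is slightly anti-conservative at 131 participants (type-I error ≈
0.07–0.08 versus nominal 0.05; the within coefficient is well
calibrated), the familiar small-sample behavior of Wald z intervals for
person-level contrasts without Kenward–Roger-type corrections. In the
no-heterogeneity limit the REML estimate lands on the zero boundary —
where the fit reduces exactly to OLS — only with moderate probability;
otherwise a small spurious variance survives and fixed effects differ
from OLS at the 1e-2 level, as with any mixed-model fitter.

## Problem sizes

Simulation studies in the test suite use 500 null replicates at n = 131
and 150 recovery replicates at n = 500 (8 waves each); the round-trip
suite renders 1000 participant-days; the acceptance script runs reduced
replicate counts and a full 131-participant demo pipeline, sizes chosen
to keep a desk-scale run comfortable.
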