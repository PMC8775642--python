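# Methods

## Problem setting

`fatiguekit` models two sides of localized muscle fatigue in forceful
hand-tool work (the motivating task is pushing a demolition hammer against
a wall):

1. **Fatigue onset** — how long a static push at a given force can be
   sustained (maximum endurance time, MET, in minutes), as a function of
   the relative load `f_MVC = push force / MVC`, where MVC is the
   operator's maximum voluntary contraction in newtons.
2. **Fatigue offset** — how strength regrows during rest after an
   exhaustive push, from its post-exertion value MS0 back toward MVC.

Both models feed work/rest scheduling: the first says how long a task can
run, the second how long a break must be.

## Endurance model

Two candidate families link MET to relative load:

- exponential: `MET = k · exp(c · f_MVC)`
- power:       `MET = k · f_MVC^c`

Natural-log transformation makes both linear in `ln MET`, so each is fitted
by ordinary least squares on the log scale, with and without an intercept
(four candidates in total). The no-intercept variants force `k = 1`, i.e.
one minute of endurance at full MVC; their slope is the through-origin
estimator `c = Σxy / Σx²`. Model selection takes the candidate with the
highest R².

**R² convention.** For regression through the origin the centered R² is
not meaningful; we report the uncentered version `1 − SSR / Σy²`, which
lies in [0, 1] and equals 1 exactly when the residuals vanish. (Statistical
packages differ here; this choice is stated rather than assumed.) A
degenerate 0/0 — zero total sum of squares — is defined as 1 when the
residuals are zero and 0 otherwise.

Predictions are restricted to `f_MVC ∈ (0, 1]`: a load above MVC has no
defined endurance and is a domain error, not an extrapolation.

Endurance models from the literature can be registered as plain callables
`f_MVC → minutes` and compared through the same deviation statistics; no
published coefficients ship with the package.

## Recovery model

Strength during rest follows first-order exponential regrowth toward
baseline:

    MS(t) = MS0 + (MVC − MS0) · (1 − e^(−RR·t))

with recovery rate RR in 1/min. Rearranging gives a regression through the
origin,

    y(t) = ln((MVC − MS0) / (MVC − MS(t))) = RR · t,

so the group-level RR is the no-intercept OLS slope of the transformed
points pooled across all trials (a per-trial mode exists for diagnostics).
RR is stored as a positive magnitude. The 0-min point is omitted from the
regression — its transform is identically zero and contributes nothing
through the origin — and observations at or above MVC, which have no finite
transform, are excluded with a count rather than an error, since
measurement noise can exceed MVC even though the model cannot.

The closed-form inversion

    t = −(1/RR) · ln(1 − (target − ms0_frac) / (1 − ms0_frac))

gives the rest time to reach any target fraction of MVC; at the reference
values RR = 0.132/min and MS0 = 58.8 % MVC, a 95 % MVC target takes
15.98 ≈ 16 min. The asymptote is MVC itself, so a target fraction ≥ 1 is
unreachable by construction.

## Validation statistics

Model fit is summarised by the absolute deviation AD = |predicted −
measured| and the relative deviation RD = AD / measured (in percent), as
mean ± sample SD (n−1 denominator throughout; the convention is a package
choice). Agreement between measured and predicted values uses:

- Pearson's r;
- ICC(2,1) — two-way random-effects, absolute-agreement, single-measures
  intraclass correlation of the n×2 subject-by-method table (computed via
  `pingouin.intraclass_corr`). Absolute agreement is the right variant for
  measured-vs-predicted comparisons because it penalises systematic offset,
  which Pearson's r ignores. An all-identical table is defined as ICC = 1
  and flagged degenerate.
- Bland–Altman analysis of differences d = measured − predicted against
  pair averages, with limits of agreement at bias ± 2·SD(d) exactly
  (±1.96·SD available by argument).

## Fit/validate split

Trials are partitioned by condition into group A = {(20 N, small tool),
(40 N, large tool)} and group B = {(20 N, large tool), (40 N, small
tool)}, so each group contains both force levels and both tools. Models
are fitted on A and validated on B. The map is configurable for other
condition sets.

A relative-weight grouping (tool weight as percent of body mass) bins
operators into L (1.9–4.7 %), N (4.8–7.5 %) and H (7.6–10.3 %). The
published bin edges are rounded to one decimal, leaving 0.1-point gaps;
values in a gap (or outside the outer edges) map to the nearest bin with a
warning flag instead of erroring, and an exact midpoint tie goes to the
lower bin.

## Synthetic-data generator

No participant-level data are publicly deposited for this task family, so
the generator produces cohorts with the statistical structure the analysis
assumes. Defaults, with units and sources of the choices:

| parameter | default | meaning |
|---|---|---|
| n_participants | 17 | cohort size of the reference study design |
| body mass | N(68.17, 10.54) kg, floor 40 | young male cohort anthropometrics |
| MVC | N(96, 17) N, floor 40 | baseline strength per condition; the floor keeps a 40 N push feasible and logs defined |
| true_exponent c | −1.15 | generating power law MET = f_MVC^c |
| met_noise_sd | 0.35 log-min | multiplicative lognormal MET noise; calibrated so per-condition MET SDs have the observed right-skewed spread (SD ≈ 3 min on a mean ≈ 7 min at 20 N) |
| ms0_frac | N(0.584, 0.101), clipped [0.2, 0.95] | post-exertion strength fraction (58.4 ± 10.1 % MVC) |
| rr_true | 0.132 /min | generating recovery rate |
| recovery_noise_sd | 2.0 N | additive strength noise, zero at t = 0 so the series anchors at MS0 |
| CR-10 map | 24.333 − 27.897 · (MS/MVC), noise SD 0.5, clipped [0, 10] | linear perceived-exertion map solved exactly from the mean time-course endpoints (7.93 at 58.8 % MVC, 1.43 at 82.1 % MVC) |

MET noise is multiplicative (lognormal) rather than additive to guarantee
positivity and match the right skew of endurance times; recovery noise is
additive on strength and clipped to (0, MVC]. Each generator operation
(cohort, fatigue trials, recovery series) draws from its own named random
substream of the top-level seed, so adding a generator never perturbs the
draws of an existing one, and a fixed seed fixes every downstream number.

The post-exertion strength fraction is reported in the source literature
both as 58.4 ± 10.1 % MVC and as 58.8 % in the mean time course; the
generator defaults to 0.584, while the reference recovery-time
extrapolation uses 0.588.

**What the generator does not emulate:** participant-level heterogeneity in
the exponent or recovery rate, within-participant correlation across
conditions, order/learning effects, heteroscedastic strength measurement
error, and any biomechanics of posture, vibration or tool dynamics. Tests
that pass on synthetic data therefore establish the correctness and
calibration of the estimators under the stated noise model, not the
validity of the power-law or exponential-recovery forms for real tasks.

## Estimator properties and known biases

- On noise-free model-generated data both fits are exact round trips
  (exponent and RR recovered to 1e-9; R² = 1).
- The log-scale endurance fit is exactly unbiased under multiplicative
  lognormal noise (OLS with additive normal errors on the log scale), and
  the Monte-Carlo suite verifies the replicate mean of ĉ sits within
  3 SEM of the truth over 500 replicates.
- The pooled RR estimator inherits a small positive Jensen-type bias from
  log-transforming additively noisy strengths: to second order the
  transform inflates E[y] by ≈ σ² / (2 (MVC − MS)²) per point, about
  0.6–1.5 % over the deficits seen at the default 2 N noise. The
  Monte-Carlo suite bounds the relative bias at this analytic 2 % order of
  magnitude and verifies it shrinks roughly quadratically when the noise
  is halved. This is a property of the log-linearized estimator itself,
  shared by any analysis using it, not an implementation artifact.

## Numerical choices and degenerate inputs

- Natural logarithms throughout.
- Through-origin slopes are computed by OLS on the single-column design
  (numerically identical to Σxy/Σx²; the tests assert agreement with the
  brute-force normal equations to 1e-9).
- Model-selection ties break toward the no-intercept fit, then the power
  form.
- A constant `f_MVC` with an intercept is a singular fit error; fewer
  trials than parameters is a sample-size error.
- A recovery series with MS0 ≥ MVC has no deficit to recover and is a
  domain error; a series whose every post-0 observation is at MVC leaves
  nothing to regress and is a fit error.
- CSV round trips are lossless: floats are written with their shortest
  exact decimal representation (`repr`), and the reader re-validates every
  invariant with the offending row index in the error message. The 0-min
  recovery row must match the trial's MS0 within 1e-6 N.

## Pipeline problem sizes

The default end-to-end run simulates 17 participants × 4 conditions
(68 trials, 476 recovery rows), fits the four endurance candidates and the
pooled recovery rate on group A (34 trials), and validates on group B.
Monte-Carlo calibration checks use 500 replicates of that design (200 for
the noise-scaling comparison); these sizes give standard errors well below
the effects being checked.

## Limitations

- The endurance model is for sustained static exertion; intermittent
  work–rest–work schedules are out of scope.
- Single-compartment recovery only; no active-recovery interventions, no
  EMG or heart-rate modelling.
- CR-10 is generated, not modelled: the linear map exists so synthetic
  data exhibit the strong negative exertion/strength correlation, and no
  CR-10 dynamics are fitted.
- No significance testing (ANOVA, post hoc comparisons) is included; the
  package reports effect summaries and agreement statistics only.
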