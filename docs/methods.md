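# Methods

This note documents the models and procedures implemented in `actimet`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Signal processing

### Input model

A raw recording is a uniformly sampled triaxial series in gravity units
(1 g = 9.81 m/s²). The emulated regime is a wrist device worn
continuously over consecutive whole days; the nominal device rate is
87.5 Hz, and all operators are rate-parametric (the test suite and
default pipeline run at 25 Hz, which leaves every per-epoch statistic
identical in expectation while keeping runtimes desk-scale). Data outside
the first and last midnight are discarded, so the working grid is whole
civil days; at most 8 measured days enter the summaries.

### Autocalibration

Static windows (10-s non-overlapping windows with all three axis SDs
below 13 mg and magnitude within 0.25 g of 1 g) should lie on the unit
sphere. Per-axis distortion `observed = gain·true + offset` is estimated
by iterated least squares: project the currently corrected static means
onto the unit sphere, regress each axis of the projection on the observed
means, repeat to convergence (tolerance 1e-10 on the mean absolute radius
residual, max 100 iterations). Correction is applied only when the
initial residual exceeds 2 mg ("corrected if necessary"); with fewer than
20 usable static windows the recording is left untouched and flagged
`converged=False` rather than aborting. Identifiability requires static
orientations spread over the sphere; overnight posture variety provides
this in practice and in the generator. On synthetic recordings with ±2%
gain and ±15 mg offset errors, recovered gains are within 5e-5 of truth.

### ENMO and epochs

Per sample, ENMO = max(‖v‖ − 1 g, 0), expressed in milligravity. Epoch
length defaults to 5 s — the processing convention for this class of
wrist data; the choice is configurable and all downstream rules are
expressed in epochs. Negative truncation makes ENMO nonnegative by
construction; with sensor noise of SD σ per axis it also induces a small
positive bias at near-zero activity (≈ σ/√2π per sample at rest, ~0.4 mg
at the default σ = 3 mg after daily averaging) — visible in the recovery
tests, and well inside their 1-mg budget.

### Nonwear

Moving 60-min windows advancing in 15-min increments are classified
nonwear when ≥ 2 of 3 axes have both SD < 13 mg and value range < 50 mg
over the window. The windowing follows the established wrist-device
nonwear heuristic; the SD/range cutoffs are the conventional defaults
from that literature and are configurable. A 15-min block is nonwear iff
**any** 60-min window containing it is nonwear. We chose this attribution
over assigning each window's label to its central block deliberately:
central attribution necessarily erodes each detected interval by ~2
blocks per side (a 3-h removal could never exceed Jaccard ≈ 0.75 against
truth), while the any-window rule recovers block-aligned intervals
exactly and cannot dilate into worn time, because a window that overlaps
genuine movement is never quiet.

### Imputation

Within valid days, each nonwear 15-min block is replaced epoch-by-epoch
with the mean over the other days where that clock block is worn — a
person- and time-of-day-specific imputation. Blocks worn on no other day
stay missing and are excluded from day means. Worn epochs are never
modified, so the operation is idempotent. The reported `imputed_fraction`
is the share of the observation period replaced.

### Validity and weekly rescaling

A day is valid at ≥ 16 h wear (inclusive; wear time is block-quantized).
A participant is included with ≥ 2 valid weekdays and ≥ 2 valid weekend
days. Validity counts wear time only, not imputed time: imputation is
defined as repairing nonwear on already-valid days. When a weekday name
occurs twice (e.g. two Tuesdays in an 8-day measurement), the first and
last occurrence are averaged to one day. Weekly values are
`(5·weekday mean + 2·weekend mean)/7`, applied identically to mean ENMO
(mg) and MVPA (min/wk). Weekend means Saturday/Sunday; day boundaries are
local midnight with no daylight-saving handling (the synthetic clock is
civil time). Partially invalid days are excluded from the weekday/weekend
means entirely.

### MVPA bouts

A moving window of the bout length (10 min main, 1 min sensitivity; slid
epoch-by-epoch within each day) qualifies when the fraction of its epochs
at or above the intensity cutoff (100 mg main, 120 mg sensitivity) is
≥ 80% (inclusive: 96 of 120 five-second epochs qualifies; 95 does not).
The 80% criterion is evaluated per epoch, not per raw sample. MVPA time
is, by default, the total duration of epochs that are themselves above
the cutoff **and** covered by at least one qualifying window. The
alternative reading — the full union of qualifying windows, sub-threshold
epochs included — is available as `mode="union"`; we did not make it the
default because window qualification extends `(1 − 0.8)·window` beyond
each edge of a sustained bout, so an isolated 30-min bout would score
34 min and the detector could not be validated against injected-bout
ground truth. Under the default accounting an isolated bout of length
≥ 80% of the window scores exactly its duration. Note one consequence of
the fractional rule under either accounting: an isolated 9-min run *is*
credited at 10-min bouts (a 10-min window holding it is 90% above
cutoff); only runs shorter than 80% of the window score zero. Bouts are
detected within days (a bout spanning midnight is split); MVPA is
computed after imputation, with a pre-imputation mode for sensitivity.
The WHO 2010 flag is weekly MVPA ≥ 150 min (inclusive).

## Questionnaire scoring

Items are (MET, hours/week) pairs; total activity is Σ MET·h/wk, MVPA
hours sum items of ≥ 3 MET (inclusive), and the WHO flag is ≥ 2.5 h/wk.
The original 20-item instrument and its compendium MET assignments are
not part of this package; scoring is exact given any item list, and the
synthetic generator ships a fixed four-item menu (walking 3.5, gardening
4.0, sports 6.0, housework 2.5 MET).

## Phenotyping

BMI bands are half-open: normal [18.5, 25), overweight [25, 30), obese
[30, ∞); BMI < 18.5 is excluded. The five risk factors use the clinical
cutoffs listed in the README; boundary conventions follow the cutoff
notation exactly (HDL and the comparisons written with "<" are strict;
BP/glucose/TG written with "≥" are inclusive; HOMA-IR > 5.12 is strict).
"Blood pressure ≥ 130/85" is read as SBP ≥ 130 **or** DBP ≥ 85 — the
standard joint-cutoff convention. Lipid-lowering medication flags only
the HDL criterion, not triglycerides, exactly as the criteria are stated.
The HOMA-IR threshold is the fixed value 5.12 (a cohort 90th percentile)
rather than a percentile recomputed on each dataset; recomputation is a
one-line variant but would make the phenotype depend on the sample.
Metabolically healthy means < 2 of the 5 factors; crossing with the three
BMI bands yields six phenotypes with healthy normal weight as reference.
Missing factor inputs drop the participant (complete-case), after
prior-wave carry-back for occupational position and health behaviours.

## Statistics

Activity variables are z-standardized with the sample (n−1) SD —
conventional for cohort descriptions; configurable. Linear differences
are OLS with classical SEs. Prevalence ratios use the modified Poisson
estimator: log-link Poisson likelihood on the binary outcome (IRLS, via
statsmodels GLM), HC0 sandwich covariance, normal-approximation CIs
exponentiated from the log scale. HC0 (rather than HC1) with normal CIs
is the canonical "robust Poisson" recipe; on any unadjusted 2×2 it
reproduces the closed-form risk ratio exactly and its robust SE equals
the delta-method form √((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀)) — both are tested
at 1e-6. AIC is 2k − 2 log L. Spearman uses mid-ranks for ties; constant
inputs are an explicit error. Under a null simulation (n = 2000, 1000
replicates) the robust Wald test's type-I error is ≈ 0.05, and linear
effect recovery at n = 5000 is unbiased to < 0.02 SD — both recomputed by
the acceptance script.

## Synthetic data

### Raw signal

Activity is synthesized in the ENMO domain as a piecewise-constant level
(sleep window, awake background, scheduled bouts) and lifted to three
axes by placing magnitude 1 g + ENMO along a unit orientation: a slow
rotation (10-min period) while awake, and piecewise-constant random
postures (20-min grid) during sleep. This guarantees an analytic ENMO
truth while exercising triaxial code paths, and it makes the two
detectors work for the right reasons: sleep postures are the static
periods autocalibration needs (magnitude exactly 1 g — the default sleep
ENMO level is 0 mg, since any constant nonzero sleep magnitude would bias
the calibration sphere), and the posture jumps give every 60-min sleep
window a large per-axis range, so quiet sleep is not mistaken for
nonwear even in noise-free recordings. Nonwear intervals render as an
exactly constant gravity vector through the same gain/offset distortion
(optionally jittered for harder cases). Per-axis gain/offset error and
Gaussian noise (default SD 3 mg) complete the measurement model.

Ground truth (wear mask, weekly ENMO after ideal imputation, bouted MVPA
minutes per setting) is computed analytically from the profile, not by
running the pipeline. Exactness imposes two validation rules: nonwear
intervals align to the 15-min block grid, and no nonwear interval shares
a clock slot with a bout on any day (otherwise the imputed value would
mix bout level into the truth). Bouts align to the epoch grid, avoid the
sleep window, and are separated by at least the longest bout window.

Default conditions: 8 days, 25 Hz (the device-native 87.5 Hz is one
parameter away), sleep 23:00–07:00 at 0 mg, awake background 30 mg,
noise 3 mg, posture changes every 20 min. The recovery experiments run
50 subjects with randomized backgrounds (20–45 mg), bouts (0–2/day,
6–40 min, 110–180 mg), removals (two of 1–3 h), ±2% gain and ±15 mg
offset errors.

What the generator does **not** emulate: realistic human gait spectra or
frequency content (levels are piecewise constant), gradual wear-position
drift, device clock drift, temperature-dependent calibration, or nonwear
that coincides in clock time with habitual exercise. Passing recovery
tests therefore demonstrates the correctness of the processing rules
under the stated measurement model, not device-level fidelity.

### Cohort

One latent activity propensity A (standard normal after a configurable
negative BMI gradient, then re-standardized) drives: weekly acceleration
(linear, mean 23.5 mg, SD 6 mg), bouted MVPA minutes (lognormal, chosen
so ~29% exceed 150 min/wk), and — through a Gaussian copula with
ρ_Pearson = 2·sin(π·ρ_S/6) — the questionnaire hours, hitting a target
Spearman correlation (default 0.30) between self-report and objective
activity. Each risk factor is Bernoulli with log-odds linear in BMI and
in A (defaults give marginal prevalences of roughly 0.55/0.40/0.25/0.14/
0.06 for hypertension, low HDL, high glucose, high triglycerides and
insulin resistance, rising with BMI and falling with activity); the
continuous marker is then drawn on the matching side of its clinical
cutoff, with a configurable share of flagged cases expressed through
medication instead. Questionnaire items split a lognormal "active block"
(walking/gardening/sports) plus near-universal housework, both monotone
in the copula latent so rank correlations are preserved; the defaults
prioritize the WHO-flag prevalence (~55%) and the rank correlation over
the mean MET-h/wk, which is consequently lower (~30) than in older
occupational cohorts (~47) — matching all three with one lognormal menu
is not possible. Covariates are independent categorical draws at
configurable frequencies, with ~2% current-wave missingness backed by a
prior wave to exercise carry-back. Because the cohort model is an
artifact-side construction (the emulated study is observational and
publishes no generative model), recovery of its parameters validates the
estimators, not any substantive epidemiology.

### Pipeline scale

`run_study` generates the cohort table with weekly summaries drawn from
the latent model and runs the raw-signal chain end-to-end on a
configurable subset (default 8 participants; profiles derived from each
participant's tabulated activity), reporting truth-vs-pipeline recovery
alongside the analysis tables. Processing thousands of 8-day recordings
per run would add nothing statistically — the signal chain's correctness
is established by the dedicated 50-subject recovery suite.

## Numerical choices and degenerate inputs

Epoch/block boundaries on non-integer samples-per-epoch rates are
resolved by timestamp (ceil to the next sample), so 87.5 Hz with 5-s
epochs is exact. All "≥" thresholds are inclusive (16 h, 100 mg, 80%,
150 min, 2 valid days, 3 MET, 2.5 h). NaN epochs (unimputable blocks)
count as below threshold in bout detection and are excluded from day
means. Recordings shorter than one full day yield an empty series and an
exclusion, not an error; constant inputs to `standardize`/`spearman` and
rank-deficient design matrices raise typed errors naming the offending
columns. Duplicate-day collapsing averages first and last occurrence; a
third occurrence of a weekday cannot arise within the 8-day cap.

## Known limitations

* Sleep staging and light/sedentary intensity classification are out of
  scope; total ENMO deliberately absorbs all movement including sleep.
* The nonwear SD/range cutoffs and the epoch length of the original
  device-processing software are not published; the defaults here follow
  the cited nonwear-detection literature and are configurable.
* The union-vs-supra-threshold bout accounting changes absolute MVPA
  minutes by design (documented above); comparisons across settings are
  monotone under the default.
* Synthetic-cohort effect sizes are configurable conveniences, not
  calibrated to any real population beyond the moments stated above.
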