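# actimet

Objective versus self-reported physical activity across metabolic
phenotypes of obesity: a tested re-implementation of the full analysis
pipeline, exercised end-to-end on synthetic data with known ground truth.

## The problem

Adults with obesity but fewer than 2 of 5 metabolic risk factors ("healthy
obesity") have intermediate disease risk, and physical activity is a
candidate modifiable determinant of that phenotype. Questionnaire measures
of activity correlate only weakly (Spearman ≈ 0.2–0.3) with objective
wrist-accelerometer measures, so analyses based on self-report can miss
real between-phenotype differences. This package implements both
measurement pipelines and the statistical comparison between them, for
epidemiologists who want to reproduce, stress-test or extend that design
without access to the original cohort data.

## What it computes

**Accelerometry** (`actimet.accelerometry`). Raw triaxial recordings in
gravity units (nominally 87.5 Hz, worn continuously over whole days) are
processed as:

1. autocalibration from static periods: per-axis gain/offset estimated by
   iteratively regressing unit-sphere projections of static-window means,
   applied only when the initial calibration error warrants it;
2. ENMO per sample — `max(‖(x,y,z)‖ − 1 g, 0)` in milligravity (mg) —
   averaged into 5-s epochs on a midnight-aligned day grid;
3. nonwear detection on moving 60-min windows with 15-min increments
   (≥ 2 of 3 axes with SD < 13 mg and range < 50 mg);
4. time-of-day imputation: each nonwear 15-min block is replaced by the
   same-clock-time mean over the other worn days;
5. validity rules: a day is valid at ≥ 16 h wear; inclusion needs ≥ 2
   valid weekdays and ≥ 2 valid weekend days (max 8 measured days);
6. weekly rescaling: duplicate weekday names averaged (first/last
   occurrence), then `(5·weekday mean + 2·weekend mean)/7`;
7. MVPA bouts: moving windows of 10 min (sensitivity: 1 min) qualify when
   ≥ 80% of their epochs are at or above 100 mg (sensitivity: 120 mg);
   MVPA time is the duration of supra-threshold epochs inside qualifying
   windows; the WHO 2010 flag is ≥ 150 min/wk.

**Questionnaire** (`actimet.questionnaire`). Total activity as
Σ MET × h/wk over reported items; MVPA hours over items ≥ 3 MET; the WHO
flag at ≥ 2.5 h/wk.

**Phenotyping** (`actimet.phenotyping`). BMI bands (normal 18.5–<25,
overweight 25–<30, obese ≥ 30; underweight excluded) crossed with
metabolic health (< 2 of: HDL < 1.03/1.29 mmol/L (M/F) or lipid meds;
BP ≥ 130/85 mm Hg or meds; glucose ≥ 5.6 mmol/L or meds; triglycerides
≥ 1.7 mmol/L; HOMA-IR > 5.12), plus the 0–6 diet score, alcohol bands and
prior-wave carry-back.

**Statistics** (`actimet.stats`). z-standardized activity differences
across the six phenotypes from OLS (two covariate sets); prevalence
ratios from modified Poisson regression — log-link Poisson likelihood
with HC0 sandwich variance, the standard choice when outcome prevalence
is too high for odds ratios; AIC (2k − 2 log L) for cross-method model
comparison; Spearman correlations; Bonferroni thresholds (0.05/5 = 0.01).

**Synthetic data** (`actimet.synthetic`). Raw-signal and cohort
generators with analytic ground truth: every processing stage has a
recovery test against known inputs. See `docs/methods.md` for the
generative model and its limits.

## Worked example

```python
from actimet.synthetic import SignalProfile, generate_raw_recording
from actimet.accelerometry import summarize_recording

profile = SignalProfile(
    days=8, sampling_rate_hz=25.0, seed=42,
    background_enmo_mg=28.0,
    mvpa_bouts=((1, 10.0, 30.0, 150.0),   # day 1, 10:00, 30 min at 150 mg
                (4, 9.0, 20.0, 110.0),    # 20 min at 110 mg
                (6, 11.0, 6.0, 150.0)),   # 6 min: too short for 10-min bouts
    nonwear_intervals=((2, 17.0, 120.0),),  # 2-h removal on day 2
    axis_gain=(1.02, 0.99, 1.00),           # miscalibrated device
    axis_offset_g=(0.01, -0.005, 0.0),
)
recording, truth = generate_raw_recording(profile)
summary, status = summarize_recording(recording)

print(f"weekly ENMO: {summary.weekly_mean_enmo_mg:.2f} mg "
      f"(truth {truth.weekly_enmo_mg:.2f} mg)")
for (thr, bout), minutes in summary.mvpa_min_per_week.items():
    print(f"MVPA at {thr:.0f} mg / {bout}-min bouts: {minutes:5.1f} min/wk "
          f"(truth {truth.bouted_mvpa_min_per_week[(thr, bout)]:5.1f})")
print(f"imputed fraction: {summary.imputed_fraction:.4f}")
print(f"estimated calibration gain: {summary.calibration.gain.round(4)}")
```

prints

```
weekly ENMO: 19.67 mg (truth 19.27 mg)
MVPA at 100 mg / 10-min bouts:   7.1 min/wk (truth   7.1)
MVPA at 100 mg / 1-min bouts:   8.0 min/wk (truth   8.0)
MVPA at 120 mg / 10-min bouts:   4.3 min/wk (truth   4.3)
MVPA at 120 mg / 1-min bouts:   5.1 min/wk (truth   5.1)
imputed fraction: 0.0104
estimated calibration gain: [1.02 0.99 1.  ]
```

The weekly acceleration lands within half a milligravity of truth despite
the injected 2% gain error, noise and a 2-h removal; the four MVPA
settings show the expected sensitivity structure (stricter cutoff ⇒ fewer
minutes, shorter bouts ⇒ more minutes, here via the 6-min bout and the
110 mg bout); the device removal (~1% of the period) was detected and
imputed; and the injected calibration distortion is recovered exactly to
the printed precision.

The full study — cohort generation, phenotyping, descriptive table,
activity-difference models, WHO prevalence-ratio tables under both
reference groups, per-risk-factor PRs and the sensitivity analyses — runs
from one call or from the shell:

```bash
actimet run-all --seed 1 --out results/study
# or stage by stage:
actimet simulate --seed 1 --n 3457 --out results/sim
actimet phenotype results/sim/cohort.csv --out results/phenotyped.csv
actimet analyze results/phenotyped.csv --out results/analysis
actimet process-accel subject01.csv --epoch-sec 5 \
    --mvpa-threshold-mg 100,120 --bout-min 10,1 --out summaries.csv
```

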