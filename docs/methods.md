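# Methods

This note documents the models, defaults and numerical choices behind
`acticut`, and what the synthetic generator does and does not emulate.

## Study design being emulated

A laboratory calibration study in healthy older adults: n = 20 (11 men,
9 women), ages drawn per sex around 63.9 (4.3) / 61.7 (2.1) years and
clipped to 55–75; height and mass per sex around 173.9 (4.2) /
161.7 (7.4) cm and 78.6 (14.3) / 72.0 (16.0) kg; BMI is derived
(mass / height²). Each session comprises reading (measured first), five
4-min treadmill stages at 3.0–5.0 km·h⁻¹ (1% grade), and four further
staged everyday activities, with six accelerometers worn
simultaneously and breath-by-breath calorimetry throughout.

## Metabolic model

- Per-activity MET anchors (mean, sd): reading 0.94 (0.14), cleaning
  3.0 (0.9), shopping 3.4 (0.2), aerobics 4.6 (1.0), cycling 4.7 (1.7).
  The reading anchor is 0.94 rather than 0.9 so that both the printed
  MET (0.9) and the printed reading VO₂ (3.3 ml·kg⁻¹·min⁻¹ = 0.94 ×
  3.5) round-trip; 0.9 × 3.5 = 3.15 would not.
- Treadmill anchors 2.8 / 3.2 / 3.6 / 4.0 / 4.5 METs (sd 0.4) for the
  five speeds. These are a design choice: walking at 1% grade in this
  age group costs somewhat more than compendium values, and the top
  speed stays mostly below the vigorous boundary so that vigorous
  cut-points are genuinely extrapolated, as in the emulated design.
- A single standard-normal fitness effect per participant scales every
  stage's MET by `anchor_mean + z·anchor_sd`. Sharing one effect across
  activities gives the strong between-activity correlation real
  cohorts show; it also means per-activity cohort sds reproduce the
  anchor sds exactly in expectation.
- Breaths arrive with exponential inter-breath intervals (mean 4 s,
  floored at 0.2 s); each breath's VO₂ is the stage mean plus N(0, 0.3)
  noise. Only stage means matter downstream (the reference uses the
  unweighted mean of breaths in the final two minutes), so no
  on-transient kinetics are modelled; stages are steady-state plus
  noise, which matches the use of last-minute / last-two-minute windows
  only.

## Accelerometer metric model

Per placement × metric, the expected per-minute value is linear in
stage VO₂:

    E[metric/min] = intercept + slope·VO₂(+ sex offsets + age slope·(age−63)) + b_subject

Default intercepts and slopes are back-solved from published cut-point
tables (`slope = (cut_vig − cut_mod)/10.5`,
`intercept = cut_mod − 10.5·slope`), e.g. hip VM slope ≈ 375 counts/min
per ml·kg⁻¹·min⁻¹ with intercept ≈ −1085, so the analytic moderate and
vigorous cut-points are 2857 and 6799 counts/min. Ankle models carry
sex-specific intercepts and slopes (female slope ≈ 3× male) plus a
small negative age slope, which is what makes the residual confounding
test stratify the ankle groups. Noise sds are back-solved from the
published per-group R² via the design's VO₂ spread (≈ 2.5–2.7
ml·kg⁻¹·min⁻¹): `sd = slope·sd_VO₂·√((1−R²)/R²)`; realized pooled R²
values land within a few hundredths of the targets (hip 0.36 vs 0.37,
erroneous hip 0.44 vs 0.45, wrist VM 0.12 vs 0.12).

Noise structure:

- total noise variance is split 1:3 between a between-subject random
  intercept and minute-level residual;
- the between-subject effect is drawn per **site group** × metric (both
  wrists of a person share their movement style), and 80% of residual
  variance is shared within a site group. Both choices leave marginal
  variances — hence the R² anchors — unchanged while reproducing the
  high dominant/non-dominant and correct/erroneous-hip correlations
  (r ≈ 0.92–0.98 in the generator; published values 0.86–0.99);
- minute values are clipped at zero, spread uniformly across the sixty
  1-s epochs with zero-sum jitter (so minute aggregates are exact), and
  the VM is decomposed into integer per-axis counts with fixed
  site-specific axis weights (vertical-dominant at the hip). Only the
  VM is analysed, so any weights satisfying the norm are acceptable;
  integer rounding perturbs a minute total by at most ~60 counts.

For everyday activities, movement is decoupled from energy cost by a
per (site group, metric, activity) coupling factor c applied as
`VO₂_eff = 3.5 + c·(VO₂ − 3.5)`: cycling ≈ 0.1 at hip and wrist
(pedalling barely moves the trunk or arms) but 1.5 at the ankle for VM;
cleaning loads the wrist (1.5–1.8) and unloads ankle/hip (0.3);
shopping is 0.8 everywhere (load carriage raises VO₂ without extra
movement); aerobics over-expresses at the wrist (1.7–1.8). These
factors were chosen once to reproduce the qualitative misclassification
pattern of staged activities (hip classifies cycling sedentary,
wrist overestimates aerobics, everything underestimates shopping); they
are realism knobs, not fitted quantities.

## Raw-signal chain

Raw 30 Hz tri-axial signals exist to exercise the calibration/ENMO
path; counts are never derived from them (the device's count filter is
proprietary). A movement stage is a unit gravity vector scaled by
`1 + e(t)` with `e(t) = ENMO·(1 − cos(2π·1.5 t))`, whose rectified mean
equals the target ENMO exactly; sensor noise is N(0, 2 mg) per axis;
still windows (12 s) cycle through an octant-covering orientation set.
Miscalibration maps the true signal through per-axis
`gain·x + offset`, with gains uniform within ±2% and offsets within
±0.05 g by default.

Auto-calibration detects still periods as consecutive 10-s blocks with
per-axis sd < 0.013 g (merged into maximal windows), requires at least
10 windows whose means spread beyond ±0.2 g on every axis, and then
iterates per-axis least squares of each window mean's projection onto
the unit sphere against its calibrated value (tolerance 1e-6 g on the
post-error change, max 100 iterations). The default 12 s still + 8 s
movement layout keeps still windows aligned with detector blocks. On
within-spec miscalibrations the fitted correction inverts the
distortion to ~1e-4 g post-calibration error; the acceptance script
verifies < 0.01 g across 50 seeded sessions. Sessions failing the
diversity check degrade to backup coefficients, or to identity with a
warning.

ENMO clips negatives per **sample** before 1-s averaging (where the
clipping happens is not standardised across toolchains; per-sample is
the stricter choice). The per-minute ENMO value is the **mean** of the
sixty 1-s mg values, not the mean × 60: published hip/wrist magnitudes
(tens to low hundreds of mg) are only consistent with minute-average
mg, so the "×60" convention is applied to the counts path only. Users
porting numbers from pipelines that sum mg per minute must divide by 60.

## Statistical choices

- OLS via statsmodels; R² is the coefficient of determination; a
  constant-VO₂ design raises a singular-fit error rather than fitting.
- Cut-points are predictions at exactly VO₂ = 10.5 and 21.0; a
  negative fitted slope (possible in low-R² wrist-ENMO groups) yields
  unordered cut-points — derivation warns, and validation skips such
  groups rather than classifying with a meaningless threshold.
- The residual confounding regression includes sex (0/1, female = 1)
  and age jointly; both p-values are reported, but only sex triggers
  stratification (the emulated design derived sex-specific, never
  age-specific, cut-points). Single-sex groups report the sex term as
  not applicable. Note the test treats the n = 100 pooled observations
  as independent; with between-subject clustering it is
  anti-conservative for between-subject covariates, a property of the
  emulated analysis itself, preserved deliberately.
- Intensity bins are half-open with boundaries in the upper class
  (3.0 METs → moderate, 6.0 → vigorous), and the metric classifier
  mirrors this (value = cut-point → upper class).
- ICC is the McGraw–Wong (A,1) single-measures absolute-agreement form
  from the two-way ANOVA mean squares,
  `(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`, computed on
  intensity classes coded 1/2/3 (equal spacing assumed). k = 2 raters
  (device vs reference; or VM vs ENMO). An all-constant table returns
  1.0 (perfect agreement) by convention.
- Timestamps are half-open `[t, t+epoch)` intervals aligned to stage
  starts; incomplete trailing epochs/minutes are dropped with warnings.

## Problem sizes

Tests and the acceptance script run entirely on generated data: the
standard cohort is 20 participants × 10 stages × 6 placements at 1-s
resolution (~1200 observations per study), Monte-Carlo properties use
100 replicate studies with reduced placement sets, and the calibration
bound uses 50 raw sessions of ~4 min at 30 Hz. These sizes were chosen
so the whole suite completes in about a minute while keeping
Monte-Carlo error well below the tolerances being asserted.

## Limitations

- The generator is a statistical emulator, not a biomechanical one: no
  gait model, no device count filter (counts are drawn at the epoch
  level), no heart-rate or blood-pressure channels, no wear-time or
  idle-sleep behaviour. Passing tests demonstrate the correctness and
  statistical behaviour of the processing chain under the assumed
  linear dose-response world, not the field validity of any particular
  cut-point value.
- SPSS ingestion requires the optional pyreadstat dependency; the CSV
  path is always available and is what the test suite uses.
- Sex stratification under the null is a 5%-probability event per
  group by construction; pipelines run on many placement × metric
  groups will occasionally stratify a truly homogeneous group, exactly
  as the emulated analysis would.
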