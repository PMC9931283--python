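# Methods

This note documents the models, conventions and design choices behind
`walkmort`, in the order the pipeline runs.

## Epochs, steady walking and inclusion

Raw recordings are fixed-rate tri-axial acceleration streams in g
(1 g = 9.81 m/s²; m/s² input is converted at read time). The stream is cut
into non-overlapping 30-second epochs — 3000 samples at the 100 Hz device
rate, 20 160 possible epochs in a week — each carrying a single activity
label supplied upstream (the activity classifier itself is out of scope;
labels are trusted input). Trailing partial windows are dropped rather than
padded, preserving the fixed 3000-sample epoch contract.

A *steady-walking session* is a maximal run of ≥ 12 consecutive
walking-labeled epochs (six minutes). "Consecutive" is taken literally: a
single non-walking epoch breaks a run, and no gap tolerance is applied. All
epochs of a qualifying run are included — a 20-epoch run contributes all 20.
Participants are excluded first for insufficient wear (default: fewer than
8640 labeled epochs, i.e. 72 hours, the standard accelerometry QC
convention; configurable) and then for lacking any qualifying session.
Evaluating wear before walking keeps the exclusion tally unambiguous.

## The 76 sensor features

Per epoch with samples aᵢ = (xᵢ, yᵢ, zᵢ) and magnitude rᵢ = ‖aᵢ‖, the
registry defines 38 "Biobank time-domain" statistics and 38 derived ones
(per-axis variants plus RMS/TAC/MCR/MMCR). Committed numerical conventions,
applied uniformly and checked feature-by-feature against independent
direct-definition oracles:

- **ENMOtrunc** = mean max(rᵢ − 1, 0); **ENMOabs** = mean |rᵢ − 1| (g).
- **Sd** uses the sample (n−1) denominator; **MPD** and the covariances use
  the population (n) denominator — so Sd and MPD are distinct statistics.
- Quantiles interpolate linearly between order statistics.
- **kurt** is excess kurtosis and **skew** plain moment skewness, both
  without bias correction; a constant series yields 0 for both, and for the
  coefficient of variation and all correlations.
- **autocorr** is the lag-1-sample (10 ms) Pearson autocorrelation.
- **Crossing rates** count sign-change sample pairs per second; a sample
  exactly on the threshold registers no crossing. MMCR averages the crossing
  rates of the two levels halfway between the mean and each extremum. Note
  the attainable maximum is set by the sampling rate (~100/s at 100 Hz, with
  white noise near 50/s), since each crossing consumes one sample pair.
- **TAC** is Σ max(rᵢ − 1, 0) for the magnitude and Σ |aᵢ − ā| per axis.
- **Orientation** angles are reported in degrees from
  atan2-of-axis-vs-complement formulas; the "g" variants evaluate the angle
  of the epoch-mean vector, avg/sd summarize per-sample angles (sample sd).
  Yaw uses the z-axis formula purely by symmetry — a static accelerometer
  cannot observe true yaw — and a zero mean vector yields zero angles with a
  warning.
- Constancy of a series is detected on the values (max = min), not on a
  rounded variance, so exactly-flat series reliably hit the 0 conventions.

The participant-level vector is the element-wise mean over all included
epochs. The epoch→participant reduction is not uniquely determined by the
study description; the mean over included epochs is the simplest estimator of
a participant's typical walking intensity and keeps the aggregate invariant
to epoch order and session count.

## Synthetic cohort generator

The generator emulates the statistical structure of the sensor sub-study so
that every downstream stage has testable ground truth. It is a statistical
stand-in, not a biomechanical gait model; passing tests demonstrate that the
pipeline recovers known structure from signals of this shape, not that it
would perform identically on real recordings (real data add device
calibration error, non-wear, label noise, and richer gait variability, all
out of scope).

- **Profiles**: age ~ U(45, 79) years, sex balanced, race 94% "white"
  (matching the cohort's composition), 22 recruitment sites assigned
  multinomially, with an optional per-site log-hazard frailty (default off).
- **Walking bouts**: bout count ~ Poisson(5/day × 7 days); run lengths from
  a mixture — 93.5% short (1 + Poisson(2), capped at 11 epochs), 6.5% long
  (12 + Geometric(0.25) − 1, capped at 40). This puts ~90% of participants
  over the one-qualifying-session inclusion bar while only a minority
  accumulate half an hour of steady walking, exercising both inclusion
  branches. The real bout-length distribution is not published; these values
  are a plausible stand-in, not a calibration target.
- **Signals**: non-walking epochs are 1 g plus N(0, 0.01 g) noise; walking
  epochs superimpose a sinusoid at a per-bout step frequency U(1.5, 2.2) Hz
  with amplitude equal to the participant's *true walking intensity* plus
  N(0, 0.03 g) noise. The magnitude is decomposed along a gravity direction
  performing a slow random walk on the unit sphere (step 0.002/sample), which
  keeps per-axis, cross-axis and orientation features non-degenerate. Epoch
  ENMOtrunc is monotone in true intensity by construction.
- **Intensity model**: true intensity (g) = 0.18 − 0.002·(age − 62) +
  0.02·male + N(0, 0.06), floored at 0.02.
- **Hazard**: event times are exponential with rate
  h₀·exp(0.09·age + 0.8·male − 12·intensity). The coefficient sizes are the
  package's own choice (the study reports no generative values): age ≈
  doubling of hazard per 8 years, male ≈ doubled hazard, and an intensity
  effect strong enough that each coefficient's sign is identifiable from a
  cohort of 2000 with ~2% events — i.e. the ground truth is recoverable at
  the scale the tests run. **h₀ is calibrated**, not fixed: given the drawn
  cohort's linear predictors, the closed-form expected event proportion
  (accounting for censoring) is solved to equal the 2% five-year target.
- **Censoring**: 5% of participants drop out uniformly over (0, 5] years;
  the remainder are administratively censored at 5 years. The real study
  does not describe dropout; this is simulator-only structure.
- **Determinism**: every stream is keyed by (seed, stream tag, participant
  index), so cohorts are pure functions of (config, seed) and recordings can
  be re-materialized lazily and bit-identically.
- **Problem sizes**: cohort-level simulation synthesizes only the included
  walking epochs' magnitudes for the fast ENMO path (`signals="enmo"`), or
  full tri-axial epochs for the 76-feature path (`signals="full"`). Tests
  and the acceptance script use cohorts of 60–5000 participants and
  recordings of minutes rather than a full week; these sizes were chosen so
  the ground-truth checks are well-powered at desk scale.

## Survival modelling

- **Penalty scale**: λ is on the per-observation (glmnet) scale. The λ grid
  is 100 log-spaced values from λ_max — computed analytically as
  max|score at β = 0| / (n·α) on standardized predictors — down to
  10⁻³·λ_max. For α = 0, λ_max is infinite, so a fixed ceiling (the α = 0.01
  value) anchors the grid. Fits requested at λ ≥ λ_max return the exact
  all-zero solution directly.
- **Backends**: elastic-net paths via scikit-survival's coxnet; ridge and
  unpenalized fits via its Newton solver with Breslow ties. Predictors are
  standardized internally; coefficients are reported on both scales. All
  coefficients are penalized uniformly — no exemption for demographics —
  matching a plain elastic-net fit.
- **Ties**: Breslow approximation throughout; synthetic event times are
  continuous so ties are rare.
- **Cross-validation**: follow-up truncation at the horizon is applied
  *before* splitting; folds are stratified by outcome so each carries ~1/10
  of events and non-events (per-class fold sizes differ by ≤ 1); (α, λ) is
  chosen by best mean CV concordance. A model with constant risk scores
  scores exactly 0.5.
- **Stepwise selection** scores candidate sets by 10-fold CV concordance
  (not in-sample fit), adds the best candidate per step, and stops when the
  increment drops below the threshold (0.01 or 0.001).
- **Concordance**: implemented in-package to pin the pair convention
  (comparable: Tᵢ < Tⱼ with event at i, plus tied times with exactly one
  event; tied scores count ½); cross-checked against brute-force enumeration
  and an independent library implementation.
- **Schoenfeld tests** refit the selected predictors unpenalized and test
  scaled Schoenfeld residuals against rank-transformed time, with the
  pass/fail threshold at p = 0.001 (configurable). Type-I error and power
  are verified by simulation, including a built-in piecewise scenario whose
  log hazard ratio switches sign mid-follow-up.
- **Percentile survival curves**: participants are split by sex and feature
  tertile; within 5-year age bins the Kaplan-Meier estimate is computed and
  the first time the curve falls below the percentile (default 0.98, i.e.
  2% cumulative mortality) is reported, linearly interpolated between event
  times. A curve sitting exactly on the percentile resolves to the next
  event time (so percentile 1.0 returns the first event time); a curve that
  never reaches it reports the stratum horizon, flagged as censored.
- **Grouped evaluation**: the per-site concordance defaults to scoring one
  full-cohort fit within each site; a per-site refit protocol is available
  via a flag, since the original description is ambiguous between the two.
  Groups without comparable pairs are flagged, not dropped silently.

## Known limitations

- The exact reference formulas for MPD, MMCR, TAC, the autocorrelation lag
  and the yaw convention are not published in the accessible material; the
  committed definitions follow the one-line glosses and standard actigraphy
  usage and are localized in `features.py` for easy revision.
- Headline discrimination values from the real cohort are not reproducible
  without the restricted data; on synthetic cohorts the pipeline asserts
  directional and structural properties (sign recovery, gain from adding an
  informative sensor feature, calibrated event rates), never the real
  cohort's C-index levels.
- No frequency-domain features, non-wear detection, device calibration,
  competing risks, or absolute-risk calibration.
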