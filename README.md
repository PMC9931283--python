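# walkmort

Mortality-risk models from **walking-intensity accelerometry**.

Large cohort studies attach wrist accelerometers to participants for a week
and ask whether the way a person walks predicts their survival. `walkmort`
implements that analysis as a tested, reusable pipeline:

1. **Steady-walking detection** — activity-labeled 30-second epochs are
   scanned for runs of ≥ 12 consecutive walking epochs (six minutes, the
   daily-living analogue of the Six Minute Walk Test). Participants without
   at least one such session, or with insufficient device wear, are excluded.
2. **Feature extraction** — each included epoch (3000 tri-axial samples at
   100 Hz, in g) yields a 76-dimensional time-domain feature vector:
   gravity-adjusted intensity (ENMO = ‖a‖ − 1 g, truncated and absolute
   variants), moments and order statistics of the magnitude and each axis,
   mean/min-max crossing rates, activity counts, axis covariances and
   lag-1 autocorrelations, and gravity-orientation angles. Per-participant
   features are the mean over included epochs.
3. **Survival modelling** — a Cox proportional hazards model with an elastic
   net penalty (mixing α ∈ {0, 0.5, 1}, strength λ on a log grid from
   λ_max), fit per maximum follow-up horizon Y ∈ {1,…,5} years (events after
   Y are censored at Y). Discrimination is Harrell's concordance index under
   outcome-stratified 10-fold cross-validation; smaller models come from
   greedy forward selection scored by CV concordance. Diagnostics include
   Schoenfeld-residual proportional-hazards tests, per-feature marginal
   rankings, feature dendrograms, percentile-survival independence curves and
   per-site concordance.

Because the real cohort data are access-restricted, the package ships a
**synthetic cohort generator** with known ground truth: week-long labeled
recordings whose walking bouts vary in run length and intensity, demographic
and categorical health covariates, and survival outcomes (~2% events over 5
years) driven by a known hazard in age, sex and true walking intensity. Every
downstream stage is testable against that ground truth without any data
download.

## The model

For participant *i* with predictors *xᵢ* (standardized internally), the
penalized partial likelihood maximized is

```
(1/n) Σ_{i: event} [ xᵢ'β − log Σ_{j: Tⱼ ≥ Tᵢ} exp(xⱼ'β) ]  −  λ ( α‖β‖₁ + (1−α)/2 ‖β‖₂² )
```

with Breslow handling of tied event times. The concordance index counts
pairs (i, j) with Tᵢ < Tⱼ and an event for i (plus tied-time pairs with
exactly one event); a pair is concordant when the shorter-lived subject has
the higher risk score, tied scores counting ½.

## Worked example

```python
from walkmort import SimConfig, simulate_cohort, fit_penalized_cox, cross_validate

cohort = simulate_cohort(SimConfig(n_participants=2000, seed=1))
included = cohort.participants[cohort.participants["included"]]
table = included[["age", "sex", "ENMOtrunc", "time", "event"]].reset_index(drop=True)
print(f"included {len(table)}/2000, events {int(table['event'].sum())}")

fit = fit_penalized_cox(table, ["age", "sex", "ENMOtrunc"])
for name, b in zip(fit.predictors, fit.coef):
    print(f"beta[{name}] = {b:+.3f}")

cv_demo = cross_validate(table, ["age", "sex"], horizon=5.0, seed=1)
cv_enmo = cross_validate(table, ["age", "sex", "ENMOtrunc"], horizon=5.0, seed=1)
print(f"CV C-index  age+sex: {cv_demo.mean_cindex:.3f}")
print(f"CV C-index  age+sex+ENMOtrunc: {cv_enmo.mean_cindex:.3f}")
```

prints

```
included 1809/2000, events 40
beta[age] = +0.098
beta[sex] = +1.249
beta[ENMOtrunc] = -33.042
CV C-index  age+sex: 0.791
CV C-index  age+sex+ENMOtrunc: 0.818
```

90% of simulated participants record at least one six-minute steady walk and
enter the model. The fitted log hazard ratios recover the generator's ground
truth: risk rises with age and male sex and falls with walking intensity
(the negative ENMOtrunc coefficient — more vigorous walking, longer
survival). Adding the sensor feature to demographics raises the
cross-validated concordance, the same qualitative gain the pipeline is built
to measure. Absolute C-index levels on synthetic cohorts reflect the
generator's effect sizes, not any real population.

## Command line

```sh
walkmort simulate --config cfg.yaml -o out/           # cohort + ground truth tables
walkmort extract  --recording rec.csv --labels labels.csv -o features.csv
walkmort sessions --labels all_labels.csv -o sessions.csv
walkmort fit      --table out/modelling_table.csv --schema out/schema.json -o fit.json
walkmort evaluate --config cfg.yaml -o eval/          # CV matrix, stepwise, PH tests, ...
walkmort report   --evaluate-dir eval/ -o report.md
```

All outputs are schema-documented CSV/JSON; a rerun with the same config and
seed is byte-identical.

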