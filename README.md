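# anchormic

Anchor-based estimation of the **minimal important change (MIC)** of the
Functional Independence Measure (FIM), the standard disability scale of
inpatient rehabilitation (13 motor items and 5 cognitive items, each rated
1–7; motor subscore 13–91, cognitive 5–35, total 18–126). The MIC is the
smallest change score patients and clinicians consider important; change
above it is clinically meaningful rather than measurement noise.

The package is written for clinimetrics and rehabilitation-outcomes
researchers who have paired admission/discharge scores and a dichotomous
external **anchor** classifying each patient as improved or not — here,
discharge home (improved, anchor = 1) versus discharge elsewhere (0).

## Estimators

Given change scores `X` (discharge − admission) and anchor `Y ∈ {0,1}`
with improvement prevalence `p`:

- **MIC_roc** — the cutoff on `X` maximizing the Youden index
  `J = sensitivity + specificity − 1`, where `X ≥ cutoff` classifies a
  patient as improved. Candidate cutoffs are midpoints between
  consecutive distinct observed values (half-integers on integer scores).
- **MIC_pred** — predictive modeling. Fit the logistic model
  `logit P(Y=1) = C + B·X`; then

  ```
  MIC_pred = (ln(odds_pre) − C) / B,    odds_pre = p / (1 − p)
  ```

- **MIC_adj** — bias-adjusted predictive modeling. When `p ≠ 0.5` the
  unadjusted estimate is biased (upward for `p > 0.5`); the correction is

  ```
  MIC_adj = MIC_pred − S·ln(odds_pre),  S = 0.09·SD_chang + 0.103·SD_chang·Cor
  ```

  with `SD_chang` the SD of the change scores and `Cor` the
  point-biserial anchor–change correlation.

95% confidence intervals come from a percentile bootstrap (2000
patient-level resamples by default). Floor/ceiling screening flags a
domain when ≥ 15% of patients sit at a scale extreme at baseline.
A calibrated synthetic-cohort generator (two-group equal-variance normal
change model, moment-matched to published summary statistics) makes the
whole pipeline testable without patient data; see `docs/methods.md`.

## Worked example

`python examples/worked_adjustment.py` applies the adjustment formula to
the published stroke-rehabilitation cohort summaries (N = 277, 187
discharged home; change SDs 14.5/4.8/16.9; correlations 0.29/0.02/0.25;
MIC_pred 19.9/4.2/24.2) and prints:

```
improvement prevalence 187/277 = 67.5%,  odds_pre = 2.0778
motor      S = 1.7381  MIC_pred =  19.9  MIC_adj =  18.6  headline MIC = 19
cognitive  S = 0.4419  MIC_pred =   4.2  MIC_adj =   3.9  headline MIC = 4
total      S = 1.9562  MIC_pred =  24.2  MIC_adj =  22.8  headline MIC = 23
```

Because two thirds of the cohort improved, `odds_pre > 1` and the
adjustment pulls each MIC down (motor: 19.9 → 18.6); the headline integer
MIC is the half-up rounding of `MIC_adj`.

The other examples run the full pipeline: `analyze_synthetic_cohort.py`
(generate → write CSV → ingest → estimate + bootstrap + floor/ceiling),
`calibration_and_recovery.py` (the generator's genuine MIC, 20.13 motor
points, recovered to +0.06 at n = 100,000) and `recovery_study.py`
(bias/RMSE of the three estimators across improvement prevalences).

The same pipeline is scriptable from the shell:

```
anchormic simulate --n 277 --seed 9 --out cohort.csv
anchormic analyze --input cohort.csv --boot 2000 --seed 3 --out results/
```

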