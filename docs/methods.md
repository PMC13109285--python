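# Methods

## The estimation problem

An anchor-based MIC analysis asks: by how many points must a FIM score
change before the change is important? The anchor — discharge home
versus elsewhere — supplies an external dichotomy of patients into
improved (`Y = 1`) and non-improved (`Y = 0`); the estimators translate
the association between the anchor and the change score `X` into a
threshold on the score scale. Discharge destination is an *objective*
anchor: unlike global-rating anchors it is available for patients with
cognitive impairment, at the cost of a weaker correlation with the score
change (0.29/0.02/0.25 for motor/cognitive/total in the calibration
cohort, below the 0.3 often recommended — the bias-adjusted estimator is
designed to remain usable in exactly this regime).

## Estimators and their assumptions

**ROC/Youden (`mic_roc`).** Nonparametric. Candidate cutoffs are the
midpoints between consecutive distinct observed change values; a patient
with change ≥ cutoff is classified improved (higher FIM = more
independent, so the scale direction is fixed). Ties on the Youden index
resolve to the smallest tying cutoff — the conservative choice, labeling
the smallest change important. Midpoints rather than observed values
make cutoffs half-integers on integer data, and make the estimator
exactly shift- and scale-equivariant.

**Predictive modeling (`mic_pred`).** Parametric in one direction only:
it assumes the logit of improvement is linear in the change score. The
estimate `(ln(odds_pre) − C)/B` is the change score at which the
posterior odds of improvement equal the cohort's prevalence odds —
equivalently, where the two group densities intersect when the
within-group distributions are normal with equal variance.
`odds_pre` uses the empirical prevalence of the analyzed dataset.

**Bias adjustment (`mic_adj`).** Subtracts `S·ln(odds_pre)` with
`S = 0.09·SD_chang + 0.103·SD_chang·Cor`. The coefficients 0.09 and
0.103 are fixed constants of the method, derived in the clinimetric
literature from simulation of perceived-change anchors; they are not
re-estimated here. `S ≥ 0` whenever `Cor ≥ −0.874`, so for any
realistic positive anchor correlation the adjustment moves the estimate
toward the 50%-prevalence value: down when most patients improved, up
when few did.

## Logistic fitting

Maximum likelihood via Newton–Raphson (statsmodels `Logit`), parameter
tolerance 1e−10, 200-iteration budget. Complete or quasi-complete
separation (anchor classes non-overlapping on the change score) raises a
hard error rather than returning a penalized fit: a MIC derived from an
unbounded slope is meaningless, and penalization would silently change
the estimand. A slope with `|B| < 1e−12` likewise raises (uninformative
anchor). Mean-centering the covariate before fitting is exposed as an
option (`fit_logistic(..., center=True)`); the recorded offset is added
back in `mic_pred`, so all MIC estimates are invariant to the choice —
the uncentered, formula-literal fit is the default and the documented
reading.

## Bootstrap

Percentile bootstrap, 2000 replicates by default at the 95% level.
Whole patients are resampled with replacement, unstratified by anchor:
prevalence then varies across replicates, which matters because
`odds_pre` (and hence both predictive estimators) consumes it.
Percentiles use linear interpolation between order statistics
(`numpy.quantile`, `method="linear"`); conventions differ across tools,
so this is stated. Replicates on which an estimator is undefined
(single-class anchor, separation, zero slope) are dropped and counted by
failure type — never imputed — and a run with fewer than 50% valid
replicates is refused with the failure taxonomy attached. Each
replicate's resampling indices come from an independent generator
spawned as `SeedSequence(seed, spawn_key=(i,))`, so results are
order-independent and any single replicate is reproducible in isolation.

## Synthetic cohorts

The generator implements the latent model the anchor-based framework
assumes: anchor `Y ~ Bernoulli(p)` and change
`X | Y ~ Normal(mu_Y, sd_within)` with equal within-group variance — the
minimal model consistent with a published mean/SD of change, prevalence,
and point-biserial correlation. `calibrate` inverts the moment
equations (group separation `d = r·sd/√(p(1−p))`, group means
`mean ± d` split by prevalence, `sd_within² = sd² − d²p(1−p)`), so
generated cohorts match all four summaries in expectation; infeasible
summaries (`|r| ≥ 1`) are rejected. The defaults are the published
stroke-ward cohort conditions: change 21.7 (14.5) motor, 4.3 (4.8)
cognitive, 26.0 (16.9) total; prevalence 187/277; correlations
0.29/0.02/0.25. These three marginal summaries are mutually consistent:
the within-group motor–cognitive correlation (≈ 0.39) implied by the
total-change SD reproduces the published total point-biserial (0.2545 vs
0.25) with no further tuning.

Under this model the logistic regression of `Y` on `X` is *correctly
specified* (slope `d/sd_within²`), and the genuine MIC — the
intersection of the two group densities, `(mu_1 + mu_0)/2` — is exactly
what `mic_pred` estimates. That gives sharp recovery tests
(`|mic_pred − genuine| < 0.5` points at n = 100,000) but also means the
*adjusted* estimator converges to `genuine − S·ln(odds_pre)`: in this
generator the adjustment looks like pure asymptotic offset (about −1.3
motor points at prevalence 0.675, confirmed by the recovery study).
The adjustment was derived under a different generative story —
individual perceived-change thresholds — which this generator
deliberately does not encode. Passing recovery tests therefore validate
the computation and calibration chain, not the clinical superiority of
one estimator; on real data, where the logit is rarely exactly linear
and the anchor is noisy, the published simulation literature favors the
adjusted estimator.

Change scores are continuous by default. Integer rounding and clamping
to the FIM change range are opt-in (`integerize`, `clamp_range`); at
motor-scale parameters they perturb the matched moments by under 0.5%.
The record-level emitter (`simulate_fim_records`) back-fills admission
scores from the published admission moments (39.1 (21.2) motor,
19.7 (8.5) cognitive) and clamps discharge scores to the scale, which
shaves the upper tail of the change distribution (total mean ≈ 24.5
rather than 26.0 at large n) — it exists to exercise the ingestion
schema and full pipeline, not for moment-exact work. What no part of
the generator emulates: skew, clustering at scale bounds, admission–
change dependence, or covariate effects on discharge destination.

## Reporting conventions

Estimates are carried at full precision and rendered at one decimal in
tables; the headline MIC is the **half-up** integer rounding of
`mic_adj` (18.6 → 19, 3.9 → 4, 22.8 → 23); banker's rounding would
break the half-way cases. Natural logarithms throughout. `SD_chang`
uses the sample (n−1) denominator, the clinimetric norm. Missing values
are excluded listwise at ingestion with a logged count; no imputation.

## Problem sizes

Desk-scale defaults keep every stage fast: the deterministic formula
chain is O(1); simulation recovery runs at n = 100,000 (logistic fit
< 1 s); bootstrap CIs at the study size (n = 277) with 2000 replicates
take a few seconds per domain; the bundled recovery-study example uses
100 replicates per scenario without per-replicate bootstrapping.

## Known limitations

- The bootstrap CIs of the calibration cohort's published table depend
  on the empirical joint distribution of its raw data, which is not
  deposited; they are not reproduction targets.
- The published ROC MICs (11.5/4.5/23.5) are sensitive to empirical
  non-normality the generator does not encode, and the generator-based
  recovery accordingly targets only the predictive estimators.
- With a near-zero anchor correlation (the cognitive domain's 0.02),
  small-cohort logistic slopes can be tiny or negative; the estimators
  raise explicit errors rather than extrapolating, and bootstrap
  replicates hitting these states are counted and dropped.
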