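"""Bias of the MIC estimators across improvement prevalences.

Simulates motor-scale cohorts at the study size (n = 277) for three
improvement prevalences and tabulates each estimator's bias and RMSE
against the generator's genuine MIC.  Because the equal-variance
two-group model makes the logistic fit correctly specified, the
unadjusted predictive estimator is centred on the genuine MIC at every
prevalence, while the adjusted estimator is shifted by −S·ln(odds_pre) —
zero at 50% prevalence, about −1.3 motor points at the study's 67.5%.
The adjustment earns its keep under the perceived-change data model it
was derived for, which this generator deliberately does not encode.
"""

from anchormic import CalibrationSummary, Scenario, run_recovery_study

scenarios = [
    Scenario(f"prev_{p}", CalibrationSummary(21.7, 14.5, p, 0.29), n=277)
    for p in (0.3, 0.5, 0.675)
]
table = run_recovery_study(scenarios, n_reps=100, seed=3)
print(table.to_string(index=False))
print(
    "\nmean_bias and rmse are in FIM motor points, measured against the\n"
    "genuine MIC of each scenario's generating model; ci_coverage is NaN\n"
    "because per-replicate bootstrapping was not requested (n_boot=0)."
)
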