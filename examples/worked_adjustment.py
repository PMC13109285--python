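"""Bias-adjust a predictive-modeling MIC from published summary statistics.

The adjustment needs only four published numbers per domain: the change
SD, the anchor-change point-biserial correlation, the improvement counts
(here 187 of 277 discharged home) and the unadjusted MIC_pred.  Running
this reproduces the published adjusted MICs (18.6, 3.9, 22.8) and the
headline integers (19, 4, 23).
"""

from anchormic import Domain, compute_S, compute_odds_pre, mic_adj, round_half_up

PUBLISHED = {
    Domain.MOTOR: dict(sd=14.5, cor=0.29, pred=19.9),
    Domain.COGNITIVE: dict(sd=4.8, cor=0.02, pred=4.2),
    Domain.TOTAL: dict(sd=16.9, cor=0.25, pred=24.2),
}

odds = compute_odds_pre(187, 277)
print(f"improvement prevalence 187/277 = {100 * 187 / 277:.1f}%,  odds_pre = {odds:.4f}")
for domain, row in PUBLISHED.items():
    s_value = compute_S(row["sd"], row["cor"])
    adjusted = mic_adj(row["pred"], s_value, odds)
    print(
        f"{domain.value:9s}  S = {s_value:.4f}  MIC_pred = {row['pred']:5.1f}  "
        f"MIC_adj = {adjusted:5.1f}  headline MIC = {round_half_up(adjusted)}"
    )
print(
    "\nMIC_adj = MIC_pred - S*ln(odds_pre): with two thirds of patients improved\n"
    "(odds_pre > 1) the unadjusted estimate overshoots, so the adjustment pulls\n"
    "each MIC down by about one point on the motor/total scales."
)
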