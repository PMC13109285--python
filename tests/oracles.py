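"""Independent oracles used to cross-check the package's estimators.

Each oracle takes a different computational route from the implementation
it checks: the logistic MLE is obtained by direct numerical optimisation
of a hand-written log-likelihood (the package uses statsmodels' Newton
solver), the Youden cutoff by exhaustive scan, and the point-biserial
correlation via scipy's dedicated routine (the package uses plain
Pearson).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats


def logit_mle(change, anchor) -> tuple[float, float]:
    """(C, B) maximizing the Bernoulli log-likelihood, via Nelder-Mead/BFGS."""
    x = np.asarray(change, dtype=float)
    y = np.asarray(anchor, dtype=float)

    def negloglik(params):
        c, b = params
        eta = c + b * x
        # log(1+exp(eta)) computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    result = optimize.minimize(negloglik, x0=[0.0, 0.0], method="BFGS")
    refined = optimize.minimize(negloglik, x0=result.x, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
    return float(refined.x[0]), float(refined.x[1])


def youden_scan(change, anchor) -> float:
    """Exhaustive Youden-index scan over all midpoint cutoffs.

    Smallest cutoff wins ties, matching the documented convention.
    """
    x = np.asarray(change, dtype=float)
    y = np.asarray(anchor)
    distinct = np.unique(x)
    best_cut, best_j = None, -math.inf
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        sens = np.mean(x[y == 1] >= cut)
        spec = np.mean(x[y == 0] < cut)
        j = sens + spec - 1.0
        if j > best_j:
            best_cut, best_j = cut, j
    return best_cut


def point_biserial_scipy(change, anchor) -> float:
    return float(stats.pointbiserialr(np.asarray(anchor), np.asarray(change)).correlation)


def mic_chain(change, anchor) -> dict:
    """Step-by-step recomputation of every MIC quantity for one dataset,
    using only numpy/scipy primitives (spreadsheet-style)."""
    x = np.asarray(change, dtype=float)
    y = np.asarray(anchor)
    n = x.size
    n_improved = int(y.sum())
    p = n_improved / n
    odds_pre = p / (1 - p)
    c, b = logit_mle(x, y)
    pred = (math.log(odds_pre) - c) / b
    sd = float(np.std(x, ddof=1))
    cor = point_biserial_scipy(x, y)
    s = 0.09 * sd + 0.103 * sd * cor
    return {
        "prevalence": p,
        "odds_pre": odds_pre,
        "C": c,
        "B": b,
        "sd_chang": sd,
        "cor": cor,
        "S": s,
        "mic_roc": youden_scan(x, y),
        "mic_pred": pred,
        "mic_adj": pred - s * math.log(odds_pre),
    }
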