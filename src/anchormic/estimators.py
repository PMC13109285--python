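"""Anchor-based MIC estimators.

Three estimators of the minimal important change (MIC) of a score, all
driven by a dichotomous external anchor (improved = 1 / not improved = 0)
paired with the observed change score:

``mic_roc``
    The ROC method: the cutoff on the change score maximizing the Youden
    index J = sensitivity + specificity − 1, where a patient with
    change ≥ cutoff is classified as improved.

``mic_pred``
    The predictive-modeling method.  Fit the logistic model
    logit P(improved) = C + B·change; the MIC is the change score at
    which the posterior odds of improvement equal the prevalence odds:

        MIC_pred = (ln(odds_pre) − C) / B,   odds_pre = p / (1 − p)

``mic_adj``
    The bias-adjusted predictive-modeling method.  MIC_pred is biased
    away from the 50%-prevalence value when the improved proportion p
    differs from one half (upward for p > 0.5, downward for p < 0.5);
    the adjustment subtracts an empirically derived correction:

        MIC_adj = MIC_pred − S·ln(odds_pre)
        S = 0.09·SD_chang + 0.103·SD_chang·Cor

    with SD_chang the SD of the change scores and Cor the point-biserial
    correlation between anchor and change.

All quantities are carried at full precision; rendering at one decimal
(and the headline integer MIC) is a reporting concern, see
:mod:`anchormic.pipeline`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import ChangeDataset, Domain
from .errors import (
    ConvergenceError,
    DegenerateAnchorError,
    DegeneratePrevalenceError,
    SeparationError,
    UndefinedCorrelationError,
    UndefinedMicError,
    ValidationError,
)

#: Adjustment coefficients of the S formula (score points per SD unit).
S_INTERCEPT_COEF = 0.09
S_CORRELATION_COEF = 0.103

#: |B| below this is treated as an uninformative anchor (MIC_pred undefined).
SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class LogisticFit:
    """Intercept and slope of the logit of the anchor on the change score.

    ``center`` is the constant subtracted from the change scores before
    fitting (0.0 for the canonical uncentered fit); C and B refer to the
    shifted covariate, and downstream formulas add ``center`` back, so
    estimates are invariant to the choice.
    """

    C: float
    B: float
    converged: bool
    n_iter: int
    center: float = 0.0


@dataclass(frozen=True)
class MicEstimate:
    """All MIC quantities for one FIM domain (one row of the results table)."""

    domain: Domain
    n: int
    mic_roc: float
    mic_pred: float
    mic_adj: float
    prevalence: float
    odds_pre: float
    S: float
    cor: float
    sd_chang: float
    fit: LogisticFit
    ci_roc: tuple[float, float] | None = None
    ci_pred: tuple[float, float] | None = None
    ci_adj: tuple[float, float] | None = None

    def with_cis(self, ci_roc, ci_pred, ci_adj) -> "MicEstimate":
        return replace(self, ci_roc=ci_roc, ci_pred=ci_pred, ci_adj=ci_adj)


def _require_both_classes(anchor: np.ndarray) -> None:
    if anchor.min() == anchor.max():
        raise DegenerateAnchorError(
            "anchor has a single class; anchor-based estimation is undefined"
        )


def point_biserial(data: ChangeDataset) -> float:
    """Point-biserial correlation of the 0/1 anchor with the change score.

    Equals the Pearson product-moment correlation applied to the binary
    anchor, which is how it is computed here.
    """
    if data.n < 3:
        raise ValidationError("point-biserial correlation needs n >= 3")
    _require_both_classes(data.anchor)
    if np.ptp(data.change) == 0:
        raise UndefinedCorrelationError("change score is constant; correlation undefined")
    return float(np.corrcoef(data.anchor, data.change)[0, 1])


def fit_logistic(
    data: ChangeDataset,
    center: bool = False,
    tol: float = 1e-10,
    maxiter: int = 200,
) -> LogisticFit:
    """Maximum-likelihood fit of logit P(anchor=1) = C + B·change.

    Newton-Raphson via statsmodels.  ``center=True`` subtracts the mean
    change before fitting (a numerical option only; MIC estimates are
    unchanged because the offset is recorded and added back).

    Raises
    ------
    SeparationError
        When the two anchor classes do not overlap on the change score
        (complete/quasi-complete separation): the MLE diverges and
        MIC_pred is meaningless.
    ConvergenceError
        When Newton iterations do not converge within ``maxiter``.
    """
    y = data.anchor
    _require_both_classes(y)
    offset = float(data.change.mean()) if center else 0.0
    x = data.change - offset

    x0, x1 = x[y == 0], x[y == 1]
    if x0.max() <= x1.min() or x1.max() <= x0.min():
        raise SeparationError(
            "anchor classes are (quasi-)separated on the change score; "
            "the logistic MLE does not exist"
        )

    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            result = sm.Logit(y, design).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise SeparationError(str(err)) from err
    n_iter = int(result.mle_retvals.get("iterations", maxiter))
    if not result.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge in {n_iter} iterations")
    intercept, slope = (float(v) for v in result.params)
    return LogisticFit(C=intercept, B=slope, converged=True, n_iter=n_iter, center=offset)


def compute_odds_pre(n_improved: int, n_total: int) -> float:
    """Prevalence odds of improvement, p/(1−p) with p = n_improved/n_total."""
    if not 0 < n_improved < n_total:
        raise DegeneratePrevalenceError(
            f"improvement count {n_improved}/{n_total} gives degenerate prevalence odds"
        )
    p = n_improved / n_total
    return p / (1.0 - p)


def mic_pred(fit: LogisticFit, odds_pre: float) -> float:
    """Predictive-modeling MIC, (ln(odds_pre) − C)/B (plus any centering offset)."""
    if odds_pre <= 0:
        raise DegeneratePrevalenceError("odds_pre must be positive")
    if abs(fit.B) < SLOPE_TOL:
        raise UndefinedMicError(
            "logistic slope is ~0: the anchor carries no information about change"
        )
    return (math.log(odds_pre) - fit.C) / fit.B + fit.center


def compute_S(sd_chang: float, cor: float) -> float:
    """Bias-correction scale S = 0.09·SD_chang + 0.103·SD_chang·Cor."""
    if sd_chang < 0:
        raise ValidationError("sd_chang must be nonnegative")
    if not -1.0 <= cor <= 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    return S_INTERCEPT_COEF * sd_chang + S_CORRELATION_COEF * sd_chang * cor


def mic_adj(mic_pred_value: float, S: float, odds_pre: float) -> float:
    """Bias-adjusted MIC, MIC_pred − S·ln(odds_pre)."""
    if odds_pre <= 0:
        raise DegeneratePrevalenceError("odds_pre must be positive")
    return mic_pred_value - S * math.log(odds_pre)


def youden_candidates(change: np.ndarray) -> np.ndarray:
    """Candidate cutoffs: midpoints between consecutive distinct change values."""
    distinct = np.unique(change)
    return (distinct[:-1] + distinct[1:]) / 2.0


def mic_roc(data: ChangeDataset) -> float:
    """ROC-method MIC: the cutoff maximizing the Youden index.

    Sensitivity is the proportion of improved patients with
    change >= cutoff; specificity the proportion of non-improved with
    change < cutoff.  Candidates are midpoints between consecutive
    distinct observed change values (half-integers on integer scores);
    on ties the smallest tying cutoff is returned (the most conservative
    labeling of change as important).
    """
    _require_both_classes(data.anchor)
    candidates = youden_candidates(data.change)
    if candidates.size == 0:
        raise UndefinedMicError("fewer than two distinct change values: no candidate cutoffs")
    improved = data.change[data.anchor == 1]
    not_improved = data.change[data.anchor == 0]
    sensitivity = (improved[:, None] >= candidates).mean(axis=0)
    specificity = (not_improved[:, None] < candidates).mean(axis=0)
    youden = sensitivity + specificity - 1.0
    return float(candidates[int(np.argmax(youden))])


def estimate_domain(data: ChangeDataset, center: bool = False) -> MicEstimate:
    """All three MIC estimators plus supporting quantities for one domain.

    Confidence intervals are not attached here; see
    :func:`anchormic.bootstrap.bootstrap_ci`.
    """
    fit = fit_logistic(data, center=center)
    odds = compute_odds_pre(data.n_improved, data.n)
    cor = point_biserial(data)
    sd = data.sd_chang
    pred = mic_pred(fit, odds)
    s_value = compute_S(sd, cor)
    return MicEstimate(
        domain=data.domain,
        n=data.n,
        mic_roc=mic_roc(data),
        mic_pred=pred,
        mic_adj=mic_adj(pred, s_value, odds),
        prevalence=data.prevalence,
        odds_pre=odds,
        S=s_value,
        cor=cor,
        sd_chang=sd,
        fit=fit,
    )
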