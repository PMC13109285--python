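"""Percentile bootstrap confidence intervals for the MIC estimators.

Whole patients (change, anchor pairs) are resampled with replacement,
unstratified by anchor status so that prevalence — which the adjusted
estimator consumes through odds_pre — varies across replicates the way it
would across repeated cohorts.  Replicates on which an estimator is
undefined (single-class anchor, separation, zero slope) are dropped and
counted by failure type, never imputed; a run with fewer than half of the
requested replicates valid is refused as unstable.

Each replicate draws its indices from an independent stream spawned from
the root seed (``SeedSequence(seed, spawn_key=(i,))``), so results do not
depend on execution order and any single replicate can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ChangeDataset
from .errors import (
    ConvergenceError,
    DegenerateAnchorError,
    DegeneratePrevalenceError,
    SeparationError,
    UndefinedCorrelationError,
    UndefinedMicError,
    ValidationError,
)
from .estimators import (
    compute_S,
    compute_odds_pre,
    fit_logistic,
    mic_adj,
    mic_pred,
    mic_roc,
    point_biserial,
)

ESTIMATOR_NAMES = ("roc", "pred", "adj")

#: Estimator failures that invalidate a single replicate (counted, not fatal).
_REPLICATE_ERRORS = (
    DegenerateAnchorError,
    DegeneratePrevalenceError,
    SeparationError,
    ConvergenceError,
    UndefinedCorrelationError,
    UndefinedMicError,
    ValidationError,
)

#: Minimum fraction of requested replicates that must yield a valid estimate.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class BootstrapResult:
    estimator: str
    replicates: np.ndarray
    n_requested: int
    n_valid: int
    ci_lower: float
    ci_upper: float
    level: float
    seed: int
    failure_counts: dict

    def ci(self, level: float) -> tuple[float, float]:
        """CI at another confidence level from the same replicate set."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.replicates, [alpha, 1.0 - alpha], method="linear")
        return float(lo), float(hi)


def evaluate_estimator(name: str, data: ChangeDataset) -> float:
    """One MIC estimator ("roc", "pred" or "adj") on one dataset."""
    if name == "roc":
        return mic_roc(data)
    fit = fit_logistic(data)
    odds = compute_odds_pre(data.n_improved, data.n)
    pred = mic_pred(fit, odds)
    if name == "pred":
        return pred
    if name == "adj":
        s_value = compute_S(data.sd_chang, point_biserial(data))
        return mic_adj(pred, s_value, odds)
    raise ValueError(f"unknown estimator {name!r}; expected one of {ESTIMATOR_NAMES}")


def bootstrap_ci(
    data: ChangeDataset,
    estimator: str,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI for one estimator.

    The CI is the empirical ``(1-level)/2`` and ``1-(1-level)/2``
    quantiles (linear interpolation between order statistics) of the
    valid replicate estimates.

    Raises
    ------
    UnstableBootstrapError
        If fewer than half of the requested replicates yield a valid
        estimate; the exception carries the failure taxonomy.
    """
    from .errors import UnstableBootstrapError

    if estimator not in ESTIMATOR_NAMES:
        raise ValueError(f"unknown estimator {estimator!r}")
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")

    n = data.n
    values = np.empty(n_boot)
    valid = 0
    failures: dict[str, int] = {}
    for i in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        idx = rng.integers(0, n, size=n)
        sample = ChangeDataset(
            domain=data.domain,
            change=data.change[idx],
            anchor=data.anchor[idx],
            check_range=False,
        )
        try:
            values[valid] = evaluate_estimator(estimator, sample)
        except _REPLICATE_ERRORS as err:
            key = type(err).__name__
            failures[key] = failures.get(key, 0) + 1
        else:
            valid += 1

    if valid < MIN_VALID_FRACTION * n_boot:
        raise UnstableBootstrapError(
            f"only {valid}/{n_boot} bootstrap replicates valid for estimator "
            f"{estimator!r}: {failures}",
            failure_counts=failures,
        )

    replicates = values[:valid].copy()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha], method="linear")
    return BootstrapResult(
        estimator=estimator,
        replicates=replicates,
        n_requested=n_boot,
        n_valid=valid,
        ci_lower=float(lo),
        ci_upper=float(hi),
        level=level,
        seed=seed,
        failure_counts=failures,
    )
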