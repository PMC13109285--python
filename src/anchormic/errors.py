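"""Exception hierarchy.

Every failure mode an estimator can hit on degenerate data has its own
class so that callers (and the bootstrap, which must count them) can
discriminate without string matching.
"""


class AnchorMicError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AnchorMicError):
    """Malformed input configuration (missing column, bad mapping, bad config file)."""


class ValidationError(AnchorMicError):
    """A record or dataset violates the FIM domain invariants."""


class EmptyInputError(AnchorMicError):
    """An operation received an empty record list or dataset."""


class DegenerateAnchorError(AnchorMicError):
    """Only one anchor class present; anchor-based estimation is undefined."""


class UndefinedCorrelationError(AnchorMicError):
    """Point-biserial correlation undefined (single-class anchor or constant change)."""


class SeparationError(AnchorMicError):
    """Complete or quasi-complete separation: the logistic MLE does not exist."""


class ConvergenceError(AnchorMicError):
    """Logistic fit failed to converge within the iteration budget."""


class UndefinedMicError(AnchorMicError):
    """MIC estimate undefined (uninformative anchor: slope below tolerance, or no cutoff candidates)."""


class DegeneratePrevalenceError(AnchorMicError):
    """Improvement prevalence of 0 or 1; prevalence odds are undefined."""


class CalibrationError(AnchorMicError):
    """Summary statistics are infeasible for the two-group equal-variance model."""


class UnstableBootstrapError(AnchorMicError):
    """Too few bootstrap replicates produced a valid estimate."""

    def __init__(self, message: str, failure_counts: dict[str, int] | None = None):
        super().__init__(message)
        self.failure_counts = dict(failure_counts or {})
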