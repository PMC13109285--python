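"""Floor and ceiling effect screening at baseline.

A floor (ceiling) effect is present when at least 15% of patients score
at the scale minimum (maximum) at baseline — here the admission
assessment; discharge scores never enter this check.  A flagged effect
limits the measurable change at one end of the scale and so undermines
MIC estimation for patients near that end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import CohortRecord, Domain, SCORE_RANGE
from .errors import EmptyInputError

#: Flagging threshold: proportion of patients at a scale extreme, percent.
FLOOR_CEILING_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class FloorCeilingReport:
    domain: Domain
    n: int
    n_at_min: int
    n_at_max: int
    pct_min: float
    pct_max: float
    floor_flag: bool
    ceiling_flag: bool
    min_score: int
    max_score: int


def assess_floor_ceiling(records: Sequence[CohortRecord], domain: Domain) -> FloorCeilingReport:
    """Screen one domain's admission scores against the 15% rule."""
    if not records:
        raise EmptyInputError("no records for floor/ceiling screening")
    domain = Domain(domain)
    lo, hi = SCORE_RANGE[domain]
    baseline = [r.score(domain, "adm") for r in records]
    n = len(baseline)
    n_min = sum(score == lo for score in baseline)
    n_max = sum(score == hi for score in baseline)
    pct_min = 100.0 * n_min / n
    pct_max = 100.0 * n_max / n
    return FloorCeilingReport(
        domain=domain,
        n=n,
        n_at_min=n_min,
        n_at_max=n_max,
        pct_min=pct_min,
        pct_max=pct_max,
        floor_flag=pct_min >= FLOOR_CEILING_THRESHOLD_PCT,
        ceiling_flag=pct_max >= FLOOR_CEILING_THRESHOLD_PCT,
        min_score=lo,
        max_score=hi,
    )
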