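"""Cohort data model: FIM score types, ingestion, and change-score construction.

The Functional Independence Measure (FIM) has 13 motor items and 5
cognitive items, each rated 1-7, giving a motor subscore of 13-91, a
cognitive subscore of 5-35 and a total of 18-126 (higher = more
independent).  A cohort row carries the two subscores at admission and at
discharge plus a dichotomous anchor: 1 if the patient was discharged home
(treated as "improved"), 0 otherwise.

Analysis operates on :class:`ChangeDataset` — paired vectors of the signed
change score (discharge minus admission) and the anchor for one domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, ValidationError

logger = logging.getLogger(__name__)

N_MOTOR_ITEMS = 13
N_COGNITIVE_ITEMS = 5


class Domain(str, Enum):
    """FIM scoring domain."""

    MOTOR = "motor"
    COGNITIVE = "cognitive"
    TOTAL = "total"


#: Valid score range (min, max) per domain.
SCORE_RANGE: dict[Domain, tuple[int, int]] = {
    Domain.MOTOR: (13, 91),
    Domain.COGNITIVE: (5, 35),
    Domain.TOTAL: (18, 126),
}

#: Valid change range per domain, implied by the score ranges.
CHANGE_RANGE: dict[Domain, tuple[int, int]] = {
    d: (lo - hi, hi - lo) for d, (lo, hi) in SCORE_RANGE.items()
}

CANONICAL_COLUMNS = (
    "patient_id",
    "motor_adm",
    "cognitive_adm",
    "motor_dis",
    "cognitive_dis",
    "anchor",
)

_SCORE_FIELDS = {
    "motor_adm": Domain.MOTOR,
    "motor_dis": Domain.MOTOR,
    "cognitive_adm": Domain.COGNITIVE,
    "cognitive_dis": Domain.COGNITIVE,
}


@dataclass(frozen=True)
class CohortRecord:
    """One patient's admission/discharge FIM subscores and anchor status."""

    patient_id: str
    motor_adm: int
    cognitive_adm: int
    motor_dis: int
    cognitive_dis: int
    anchor: int

    def __post_init__(self) -> None:
        for name, domain in _SCORE_FIELDS.items():
            value = getattr(self, name)
            lo, hi = SCORE_RANGE[domain]
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name}={value} outside the "
                    f"{domain.value} FIM range [{lo}, {hi}]"
                )
        for name in ("total_adm", "total_dis"):
            lo, hi = SCORE_RANGE[Domain.TOTAL]
            value = getattr(self, name)
            if not (lo <= value <= hi):  # pragma: no cover - implied by subscales
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name}={value} outside [{lo}, {hi}]"
                )
        if self.anchor not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: anchor={self.anchor!r} is not 0/1"
            )

    @property
    def total_adm(self) -> int:
        return self.motor_adm + self.cognitive_adm

    @property
    def total_dis(self) -> int:
        return self.motor_dis + self.cognitive_dis

    def score(self, domain: Domain, when: str) -> int:
        """Score for ``domain`` at ``when`` in {"adm", "dis"}."""
        if domain is Domain.TOTAL:
            return self.total_adm if when == "adm" else self.total_dis
        return getattr(self, f"{domain.value}_{when}")

    def change(self, domain: Domain) -> int:
        return self.score(domain, "dis") - self.score(domain, "adm")


@dataclass(frozen=True)
class ChangeDataset:
    """Paired (change score, anchor) vectors for one FIM domain.

    ``check_range`` may be disabled for latent continuous change scores
    from the synthetic generator, which can fall marginally outside the
    integer scale's bounds; ingested data are always checked.
    """

    domain: Domain
    change: np.ndarray
    anchor: np.ndarray
    check_range: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        change = np.asarray(self.change, dtype=float)
        anchor = np.asarray(self.anchor, dtype=np.int64)
        object.__setattr__(self, "change", change)
        object.__setattr__(self, "anchor", anchor)
        if change.ndim != 1 or anchor.ndim != 1 or change.shape != anchor.shape:
            raise ValidationError("change and anchor must be equal-length 1-D vectors")
        if change.size < 1:
            raise EmptyInputError("empty change dataset")
        if not np.isin(anchor, (0, 1)).all():
            raise ValidationError("anchor values must be 0 or 1")
        if self.check_range:
            lo, hi = CHANGE_RANGE[self.domain]
            bad = np.flatnonzero((change < lo) | (change > hi))
            if bad.size:
                raise ValidationError(
                    f"{self.domain.value} change out of range [{lo}, {hi}] "
                    f"at positions {bad[:5].tolist()}"
                )

    @property
    def n(self) -> int:
        return int(self.change.size)

    @property
    def n_improved(self) -> int:
        return int(self.anchor.sum())

    @property
    def prevalence(self) -> float:
        return float(self.anchor.mean())

    @property
    def sd_chang(self) -> float:
        """Sample (n-1 denominator) standard deviation of the change scores."""
        return float(np.std(self.change, ddof=1))


def build_change_dataset(records: Sequence[CohortRecord], domain: Domain) -> ChangeDataset:
    """Change scores (discharge − admission) and anchors for one domain.

    For the total domain the subscores are summed at each timepoint
    before differencing (equivalent to summing the per-domain changes).
    """
    if not records:
        raise EmptyInputError("no records to build a change dataset from")
    domain = Domain(domain)
    change = np.array([r.change(domain) for r in records], dtype=float)
    anchor = np.array([r.anchor for r in records], dtype=np.int64)
    return ChangeDataset(domain=domain, change=change, anchor=anchor)


def _item_columns(when: str) -> list[str]:
    motor = [f"motor_item{i}_{when}" for i in range(1, N_MOTOR_ITEMS + 1)]
    cog = [f"cognitive_item{i}_{when}" for i in range(1, N_COGNITIVE_ITEMS + 1)]
    return motor + cog


def read_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    item_level: bool = False,
) -> list[CohortRecord]:
    """Read a delimited-text cohort table into validated records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from canonical column names (``patient_id``,
        ``motor_adm``, ``cognitive_adm``, ``motor_dis``, ``cognitive_dis``,
        ``anchor``) to the names actually used in the file.
    delimiter
        Field separator; comma by default, ``"\\t"`` for tab.
    item_level
        If true, expect 18 item columns per timepoint
        (``motor_item1_adm`` ... ``cognitive_item5_dis``, each scored 1-7)
        and sum them into domain scores.  Domain-level input is canonical.

    Rows with any missing mapped value are excluded listwise with a logged
    count; out-of-range scores and non-binary anchors raise
    :class:`~anchormic.errors.ValidationError` naming the row and field.
    """
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=delimiter)

    def resolve(canonical: str) -> str:
        actual = column_map.get(canonical, canonical)
        if actual not in frame.columns:
            raise ConfigurationError(
                f"column {actual!r} (for {canonical!r}) not found in {path}"
            )
        return actual

    if item_level:
        needed = ["patient_id", "anchor"]
        item_cols = {w: [resolve(c) for c in _item_columns(w)] for w in ("adm", "dis")}
    else:
        needed = list(CANONICAL_COLUMNS)
    resolved = {c: resolve(c) for c in needed}

    if item_level:
        for when in ("adm", "dis"):
            cols = item_cols[when]
            items = frame[cols]
            bad = ((items < 1) | (items > 7)) & items.notna()
            if bad.any().any():
                row = int(bad.any(axis=1).idxmax())
                col = bad.columns[bad.loc[row].argmax()]
                raise ValidationError(
                    f"row {row}: item score {col}={items.loc[row, col]} outside 1-7"
                )
            frame[f"motor_{when}"] = items[cols[:N_MOTOR_ITEMS]].sum(axis=1, min_count=N_MOTOR_ITEMS)
            frame[f"cognitive_{when}"] = items[cols[N_MOTOR_ITEMS:]].sum(
                axis=1, min_count=N_COGNITIVE_ITEMS
            )
        resolved.update({c: c for c in CANONICAL_COLUMNS if c != "patient_id" and c != "anchor"})

    used = frame[[resolved[c] for c in CANONICAL_COLUMNS]].copy()
    used.columns = list(CANONICAL_COLUMNS)

    complete = used.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "read_cohort: excluded %d of %d rows with missing values (listwise)",
            n_dropped,
            len(used),
        )
    used = used[complete]

    records: list[CohortRecord] = []
    for row_index, row in used.iterrows():
        values = {}
        for name in CANONICAL_COLUMNS[1:]:
            raw = row[name]
            numeric = float(raw)
            if numeric != int(numeric):
                raise ValidationError(f"row {row_index}: {name}={raw!r} is not an integer")
            values[name] = int(numeric)
        try:
            records.append(CohortRecord(patient_id=str(row["patient_id"]), **values))
        except ValidationError as err:
            raise ValidationError(f"row {row_index}: {err}") from err
    return records


def write_cohort(records: Iterable[CohortRecord], path, delimiter: str = ",") -> None:
    """Re-emit a normalized cohort as delimited text (audit trail / round-trip)."""
    frame = pd.DataFrame([vars(r) for r in records], columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False)
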