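import numpy as np
import pytest

from anchormic import CohortRecord, Domain, calibrate, simulate_cohort
from anchormic.simulate import FIM_SUMMARIES

# (patient_id, motor_adm, cognitive_adm, motor_dis, cognitive_dis, anchor)
# Hand-built 20-patient cohort: anchor classes overlap on every domain's
# change score (no separation), scores well inside the FIM ranges.
HAND_ROWS = [
    ("p01", 40, 20, 65, 26, 1),
    ("p02", 35, 18, 55, 22, 1),
    ("p03", 50, 25, 72, 30, 1),
    ("p04", 30, 15, 58, 20, 1),
    ("p05", 45, 22, 60, 25, 1),
    ("p06", 38, 19, 70, 27, 1),
    ("p07", 55, 28, 80, 33, 1),
    ("p08", 42, 21, 52, 23, 1),
    ("p09", 33, 17, 51, 21, 1),
    ("p10", 60, 30, 85, 34, 1),
    ("p11", 28, 14, 40, 16, 1),
    ("p12", 47, 24, 77, 31, 1),
    ("p13", 36, 18, 44, 20, 0),
    ("p14", 50, 26, 68, 29, 0),
    ("p15", 25, 12, 30, 13, 0),
    ("p16", 44, 22, 56, 24, 0),
    ("p17", 30, 16, 45, 19, 0),
    ("p18", 52, 27, 62, 28, 0),
    ("p19", 22, 10, 24, 10, 0),
    ("p20", 40, 20, 62, 26, 0),
]


def make_records(rows):
    return [
        CohortRecord(
            patient_id=pid,
            motor_adm=ma,
            cognitive_adm=ca,
            motor_dis=md,
            cognitive_dis=cd,
            anchor=a,
        )
        for pid, ma, ca, md, cd, a in rows
    ]


@pytest.fixture
def hand_cohort6():
    return make_records(HAND_ROWS[:4] + HAND_ROWS[13:15])


@pytest.fixture
def hand_cohort20():
    return make_records(HAND_ROWS)


@pytest.fixture(scope="session")
def motor_cohort_277():
    """Calibrated motor-domain change dataset at the published cohort size."""
    spec = calibrate(FIM_SUMMARIES[Domain.MOTOR], n=277, seed=20230277, domain=Domain.MOTOR)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def motor_cohort_large():
    """Calibrated motor-domain cohort at n=100,000 for recovery checks."""
    spec = calibrate(FIM_SUMMARIES[Domain.MOTOR], n=100_000, seed=20231, domain=Domain.MOTOR)
    return spec, simulate_cohort(spec)
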