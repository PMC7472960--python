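"""Published demographic marginals of a 1,107-patient surgical meningioma cohort.

These counts — the location distribution over the 15 dural categories, WHO
grade shares, sex-by-grade composition, extent-of-resection split, and
per-grade recurrence counts — are the reference frequencies the synthetic
generator targets, and :func:`demographic_fixture_cohort` materialises them
as an exact deterministic cohort for testing summary statistics.
"""

from __future__ import annotations

import numpy as np

from .io import Cohort, LOCATION_CATEGORIES, PatientRecord

__all__ = [
    "LOCATION_COUNTS",
    "GRADE_COUNTS",
    "FEMALE_BY_GRADE",
    "RECURRENCE_BY_GRADE",
    "EOR_COUNTS",
    "N_PATIENTS",
    "MEDIAN_AGE_YEARS",
    "AGE_RANGE_YEARS",
    "MEDIAN_VOLUME_CM3",
    "RECURRENCE_RATE_BY_GRADE",
    "demographic_fixture_cohort",
]

N_PATIENTS = 1107

LOCATION_COUNTS: dict[str, int] = {
    "convexity": 230,
    "parasagittal_sinus": 179,
    "falx": 126,
    "tentorium": 94,
    "cerebellar_convexity": 10,
    "cerebellopontine_angle": 86,
    "sphenoid_wing": 109,
    "parasellar_cavernous_sinus": 32,
    "tuberculum_sellae": 84,
    "middle_fossa": 14,
    "olfactory_groove": 66,
    "clival_petroclival": 21,
    "foramen_magnum": 3,
    "intraventricular": 22,
    "others": 31,
}

GRADE_COUNTS: dict[str, int] = {"I": 993, "II": 101, "III": 13}

# 717 of 993 grade-I patients were female; 68 of the 114 grade-II/III
# patients were female (split 60/8 across II/III to preserve the margin).
FEMALE_BY_GRADE: dict[str, int] = {"I": 717, "II": 60, "III": 8}

RECURRENCE_BY_GRADE: dict[str, int] = {"I": 28, "II": 8, "III": 7}

# EOR was recorded for 1,050 of the 1,107 patients.
EOR_COUNTS: dict[str, int] = {"GTR": 945, "STR": 105, "missing": 57}

MEDIAN_AGE_YEARS = 56.0
AGE_RANGE_YEARS = (13.0, 85.0)

#: Median normalised preoperative tumour volume (cm^3).
MEDIAN_VOLUME_CM3 = 22.828

RECURRENCE_RATE_BY_GRADE: dict[str, float] = {"I": 0.028, "II": 0.079, "III": 0.538}

assert sum(LOCATION_COUNTS.values()) == N_PATIENTS
assert sum(GRADE_COUNTS.values()) == N_PATIENTS
assert sum(EOR_COUNTS.values()) == N_PATIENTS


def demographic_fixture_cohort(followup_months: float = 60.0) -> Cohort:
    """Deterministic cohort realising the reference marginals exactly.

    Grade, sex-within-grade, per-grade recurrence, and EOR counts match the
    reference table; location labels are assigned independently of grade
    (the joint distribution is not published). Ages fill the published range
    uniformly. No masks are attached — the fixture serves the tabular
    summaries, not the voxel-wise maps.
    """
    # location labels in a fixed shuffled order, decoupled from grade order
    labels: list[str] = []
    for name in LOCATION_CATEGORIES:
        labels.extend([name] * LOCATION_COUNTS[name])
    rng = np.random.default_rng(0)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    lo, hi = AGE_RANGE_YEARS
    records: list[PatientRecord] = []
    i = 0
    for grade in ("I", "II", "III"):
        n_grade = GRADE_COUNTS[grade]
        n_female = FEMALE_BY_GRADE[grade]
        n_recur = RECURRENCE_BY_GRADE[grade]
        for j in range(n_grade):
            records.append(
                PatientRecord(
                    patient_id=f"P{i:04d}",
                    age=round(lo + (hi - lo) * i / (N_PATIENTS - 1), 1),
                    sex="female" if j < n_female else "male",
                    who_grade=grade,
                    location_label=labels[i],
                    recurrence=j < n_recur,
                    followup_time=followup_months,
                )
            )
            i += 1

    # EOR: last 57 records missing, then GTR/STR filling the observed counts
    n_missing = EOR_COUNTS["missing"]
    n_gtr = EOR_COUNTS["GTR"]
    for k, r in enumerate(records):
        if k >= N_PATIENTS - n_missing:
            r.eor = None
        else:
            r.eor = "GTR" if k < n_gtr else "STR"
    return Cohort(records=records)
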