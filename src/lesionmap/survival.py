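"""Recurrence-free survival: Kaplan–Meier curves and log-rank tests.

Follow-up starts at surgery; the event is recurrence, and patients without
recurrence are censored at last follow-up. The cohort is dichotomised by
the standard rules — age at the published median (56 years), WHO grade I
vs II+III, Ki67 > 5%, preoperative volume at the published median
(22.828 cm^3), GTR vs STR — and each split is compared with the one-degree
log-rank test. Estimation is delegated to lifelines; at tied times events
are processed before censorings (the usual product-limit convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import Cohort, PatientRecord

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "StratificationRule",
    "stratify_cohort",
    "standard_rules",
    "rfs_comparison",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate, tabulated at the distinct event times."""

    times: np.ndarray  # ascending distinct event times
    at_risk: np.ndarray  # risk-set size just before each event time
    events: np.ndarray  # events at each time
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first event)."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be equal-length 1D")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    return SurvivalCurve(
        times=rows.index.to_numpy(dtype=float),
        at_risk=rows["at_risk"].to_numpy(dtype=int),
        events=rows["observed"].to_numpy(dtype=int),
        survival=kmf.survival_function_.loc[rows.index, "KM_estimate"].to_numpy(),
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank chi-square and p for two groups."""
    t_a, e_a = (np.asarray(v) for v in group_a)
    t_b, e_b = (np.asarray(v) for v in group_b)
    if len(t_a) == 0 or len(t_b) == 0:
        raise ValueError("both groups must be nonempty")
    if e_a.sum() + e_b.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class StratificationRule:
    """Dichotomisation of the cohort on one covariate.

    ``kind="threshold"``: group A has covariate >= ``cutoff``.
    ``kind="levels"``: group A has covariate in ``a_levels``, B in
    ``b_levels``; anything else (including missing) is excluded.
    The covariate is a record field, a marker name, or ``"volume_cm3"``
    resolved through an extra per-patient mapping.
    """

    name: str
    covariate: str
    kind: str = "threshold"
    cutoff: Optional[float] = None
    a_levels: Optional[frozenset] = None
    b_levels: Optional[frozenset] = None

    def _value(self, record: PatientRecord, extra: Optional[Mapping[str, float]]):
        if extra is not None and record.patient_id in extra:
            return extra[record.patient_id]
        if record.markers and self.covariate in record.markers:
            return record.markers[self.covariate]
        return getattr(record, self.covariate, None)

    def assign(self, record: PatientRecord, extra=None) -> Optional[str]:
        value = self._value(record, extra)
        if value is None:
            return None
        if self.kind == "threshold":
            return "A" if float(value) >= self.cutoff else "B"
        if value in self.a_levels:
            return "A"
        if value in self.b_levels:
            return "B"
        return None


def standard_rules(
    age_cutoff: float = 56.0, volume_cutoff_cm3: float = 22.828
) -> list[StratificationRule]:
    return [
        StratificationRule(f"age_ge_{age_cutoff:g}", "age", "threshold", cutoff=age_cutoff),
        StratificationRule(
            "grade_II_III_vs_I",
            "who_grade",
            "levels",
            a_levels=frozenset({"II", "III"}),
            b_levels=frozenset({"I"}),
        ),
        StratificationRule(
            "ki67_gt5pct",
            "ki67_gt5pct",
            "levels",
            a_levels=frozenset({True}),
            b_levels=frozenset({False}),
        ),
        StratificationRule(
            f"volume_ge_{volume_cutoff_cm3:g}cm3",
            "volume_cm3",
            "threshold",
            cutoff=volume_cutoff_cm3,
        ),
        StratificationRule(
            "eor_gtr_vs_str",
            "eor",
            "levels",
            a_levels=frozenset({"GTR"}),
            b_levels=frozenset({"STR"}),
        ),
    ]


def stratify_cohort(
    cohort: Cohort,
    rule: StratificationRule,
    extra: Optional[Mapping[str, float]] = None,
) -> tuple[list[PatientRecord], list[PatientRecord], int]:
    """Split records into (group A, group B, n excluded) under ``rule``."""
    a, b, excluded = [], [], 0
    for r in cohort.records:
        g = rule.assign(r, extra)
        if g == "A":
            a.append(r)
        elif g == "B":
            b.append(r)
        else:
            excluded += 1
    return a, b, excluded


def rfs_comparison(
    cohort: Cohort,
    rule: StratificationRule,
    extra: Optional[Mapping[str, float]] = None,
) -> dict:
    """Kaplan–Meier curves for both groups plus the log-rank test.

    Records lacking a recurrence status are excluded. Returns curves, group
    sizes and the (statistic, p) of the log-rank test; if a group is empty
    the test is blocked and reported as such.
    """
    a, b, excluded = stratify_cohort(cohort, rule, extra)
    a = [r for r in a if r.recurrence is not None]
    b = [r for r in b if r.recurrence is not None]
    result = {
        "rule": rule.name,
        "n_a": len(a),
        "n_b": len(b),
        "n_excluded": excluded,
    }
    if not a or not b:
        result["error"] = "empty group; log-rank blocked"
        return result

    def arm(records):
        return (
            [r.followup_time for r in records],
            [int(bool(r.recurrence)) for r in records],
        )

    arm_a, arm_b = arm(a), arm(b)
    result["curve_a"] = km_estimate(*arm_a)
    result["curve_b"] = km_estimate(*arm_b)
    try:
        stat, p = logrank_test(arm_a, arm_b)
        result["statistic"], result["p"] = stat, p
    except ValueError as exc:
        result["error"] = str(exc)
    return result
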