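"""Stereospecific frequency heatmaps and cohort location summaries.

Superimposing all patients' binary lesion masks yields a per-voxel count
map; dividing by the cohort size gives the percentage of patients whose
lesion occupies each voxel — the lesion frequency atlas that is displayed
(typically capped at 5%) over the template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GridMismatchError
from .io import Cohort, LesionMask, LOCATION_CATEGORIES

__all__ = [
    "FrequencyMap",
    "build_frequency_map",
    "clip_for_display",
    "location_summary",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class FrequencyMap:
    counts: np.ndarray  # per-voxel number of patients with tumour here
    n: int  # cohort size (denominator)

    @property
    def percentage(self) -> np.ndarray:
        return 100.0 * self.counts / self.n


def build_frequency_map(masks: Sequence[LesionMask], n: int) -> FrequencyMap:
    """Count, per voxel, how many masks occupy it.

    ``n`` is the percentage denominator: the full cohort size, which may
    exceed the number of masks passed in (patients whose lesions lie
    elsewhere still count toward "share of patients with tumour here").
    """
    masks = list(masks)
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if n < len(masks):
        raise ValueError(f"n={n} smaller than number of masks ({len(masks)})")
    if not masks:
        raise ValueError("no masks given")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        if m.grid.shape != grid.shape or not np.allclose(
            m.grid.affine, grid.affine, atol=1e-3
        ):
            raise GridMismatchError(f"mask {m.patient_id} is on a different grid")
        counts += m.occupancy
    return FrequencyMap(counts=counts, n=int(n))


def clip_for_display(fmap: FrequencyMap, cap: float = 5.0) -> np.ndarray:
    """Percentage map clipped at ``cap`` for a fixed colour scale."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(fmap.percentage, cap)


def location_summary(cohort: Cohort) -> pd.DataFrame:
    """Tabulate the cohort the way demographic tables are printed.

    Sections: location counts/percentages over the 15 categories, WHO grade
    shares, female share within grade I and within grades II+III, extent of
    resection over the EOR-evaluable subset, and per-grade recurrence rates.
    Percentages are rounded half away from zero to one decimal, and every
    row carries its denominator.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    n = cohort.n
    rows: list[dict] = []

    def add(section, label, count, denom):
        rows.append(
            {
                "section": section,
                "label": label,
                "count": int(count),
                "denominator": int(denom),
                "percent": round_half_up(100.0 * count / denom) if denom else float("nan"),
            }
        )

    for cat in LOCATION_CATEGORIES:
        add("location", cat, sum(r.location_label == cat for r in cohort.records), n)

    by_grade = {g: [r for r in cohort.records if r.who_grade == g] for g in ("I", "II", "III")}
    for g in ("I", "II", "III"):
        add("who_grade", g, len(by_grade[g]), n)

    add("sex", "female", sum(r.sex == "female" for r in cohort.records), n)
    add("sex", "male", sum(r.sex == "male" for r in cohort.records), n)

    grade1 = by_grade["I"]
    high = by_grade["II"] + by_grade["III"]
    if grade1:
        add("sex_by_grade", "female_grade_I", sum(r.sex == "female" for r in grade1), len(grade1))
    if high:
        add(
            "sex_by_grade",
            "female_grade_II_III",
            sum(r.sex == "female" for r in high),
            len(high),
        )

    evaluable = cohort.eor_evaluable()
    add("eor", "GTR", sum(r.eor == "GTR" for r in evaluable), len(evaluable) or 1)
    add("eor", "STR", sum(r.eor == "STR" for r in evaluable), len(evaluable) or 1)

    for g in ("I", "II", "III"):
        grp = by_grade[g]
        if grp:
            add(
                "recurrence_by_grade",
                g,
                sum(bool(r.recurrence) for r in grp),
                len(grp),
            )

    return pd.DataFrame(rows)
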