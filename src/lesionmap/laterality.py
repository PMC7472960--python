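"""Hemispheric laterality of lesions.

Each lesion is assigned left / right / midline from the world-x coordinate
of its occupancy-weighted centroid (RAS+: negative x is the left
hemisphere), with a small epsilon buffer around the mid-sagittal plane so
registration slop does not lateralise genuinely midline lesions. The
left/right balance is tested against a fair coin with the exact two-sided
binomial test, overall and within strata; midline lesions are excluded from
the test and reported separately.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .grid import TemplateGrid
from .io import Cohort, LesionMask

__all__ = ["hemisphere_assignment", "laterality_test", "laterality_table"]

DEFAULT_EPSILON_MM = 2.0


def hemisphere_assignment(
    mask: LesionMask,
    grid: Optional[TemplateGrid] = None,
    epsilon: float = DEFAULT_EPSILON_MM,
) -> str:
    """Side of the lesion centroid: "left", "right" or "midline"."""
    grid = grid or mask.grid
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.patient_id} is empty")
    idx = np.argwhere(mask.occupancy)
    x = grid.voxel_to_world(idx)[:, 0].mean()
    if x < -epsilon:
        return "left"
    if x > epsilon:
        return "right"
    return "midline"


def laterality_test(n_left: int, n_right: int) -> float:
    """Exact two-sided binomial p for left/right counts against 0.5."""
    if n_left < 0 or n_right < 0:
        raise ValueError("counts must be nonnegative")
    total = n_left + n_right
    if total == 0:
        raise ValueError("no lateralised lesions to test")
    return float(stats.binomtest(n_left, total, 0.5).pvalue)


def laterality_table(
    cohort: Cohort,
    masks: Mapping[str, LesionMask],
    strata: Optional[Mapping[str, Callable]] = None,
    epsilon: float = DEFAULT_EPSILON_MM,
) -> pd.DataFrame:
    """Left/right/midline counts and binomial p, overall and per stratum.

    ``strata`` maps a stratum name to a function of a record returning the
    stratum level (or None to drop the record); default strata are location
    category, sex and WHO grade.
    """
    sides = {
        pid: hemisphere_assignment(m, epsilon=epsilon) for pid, m in masks.items()
    }
    if strata is None:
        strata = {
            "location": lambda r: r.location_label,
            "sex": lambda r: r.sex,
            "who_grade": lambda r: r.who_grade,
        }

    def summarise(name, level, records):
        counts = {"left": 0, "right": 0, "midline": 0}
        for r in records:
            if r.patient_id in sides:
                counts[sides[r.patient_id]] += 1
        lateralised = counts["left"] + counts["right"]
        return {
            "stratum": name,
            "level": level,
            "n_left": counts["left"],
            "n_right": counts["right"],
            "n_midline": counts["midline"],
            "binomial_p": (
                laterality_test(counts["left"], counts["right"])
                if lateralised
                else float("nan")
            ),
        }

    rows = [summarise("overall", "all", cohort.records)]
    for name, accessor in strata.items():
        levels: dict[str, list] = {}
        for r in cohort.records:
            level = accessor(r)
            if level is not None:
                levels.setdefault(str(level), []).append(r)
        for level in sorted(levels):
            rows.append(summarise(name, level, levels[level]))
    return pd.DataFrame(rows)
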