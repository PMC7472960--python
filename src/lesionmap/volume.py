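"""Normalised tumour volumes and group-comparison statistics.

The normalised volume of a lesion is the number of occupied voxels times
the single-voxel volume of the template grid. Volumes across location
groups are compared with the Kruskal–Wallis rank test followed by Dunn's
pairwise post hoc (Bonferroni-adjusted); categorical demographics use the
Pearson chi-square test without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fisher import ContingencyTable
from .grid import TemplateGrid
from .io import LesionMask

__all__ = [
    "VolumeRecord",
    "lesion_volume",
    "volume_table",
    "kruskal_wallis_test",
    "dunn_posthoc",
    "chi_square_association",
]


@dataclass(frozen=True)
class VolumeRecord:
    patient_id: str
    voxel_count: int
    volume_mm3: float
    location_label: Optional[str] = None

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0


def lesion_volume(
    mask: LesionMask,
    grid: Optional[TemplateGrid] = None,
    location_label: Optional[str] = None,
) -> VolumeRecord:
    """Volume = voxel count x single-voxel volume (mm^3), exactly."""
    grid = grid or mask.grid
    count = mask.voxel_count
    return VolumeRecord(
        patient_id=mask.patient_id,
        voxel_count=count,
        volume_mm3=count * grid.voxel_volume,
        location_label=location_label,
    )


def volume_table(
    masks: Mapping[str, LesionMask],
    locations: Optional[Mapping[str, str]] = None,
    grid: Optional[TemplateGrid] = None,
) -> pd.DataFrame:
    rows = []
    for pid in sorted(masks):
        rec = lesion_volume(
            masks[pid], grid, (locations or {}).get(pid)
        )
        rows.append(
            {
                "patient_id": pid,
                "voxel_count": rec.voxel_count,
                "volume_mm3": rec.volume_mm3,
                "volume_cm3": rec.volume_cm3,
                "location_label": rec.location_label,
            }
        )
    return pd.DataFrame(rows)


def _check_groups(groups: Mapping[str, Sequence[float]], minimum: int) -> None:
    if len(groups) < minimum:
        raise ValueError(f"need at least {minimum} groups, got {len(groups)}")
    for label, values in groups.items():
        if len(values) == 0:
            raise ValueError(f"group {label!r} is empty")


def kruskal_wallis_test(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square tail probability."""
    _check_groups(groups, 2)
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; ranks are degenerate")
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after an omnibus Kruskal–Wallis.

    z is the mean-rank difference over the tie-corrected pooled standard
    error; two-sided normal p; adjusted p is Bonferroni over the
    k(k-1)/2 pairs (``adjust="none"`` to disable).
    """
    _check_groups(groups, 3)
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)

    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    start = 0
    for g, v in zip(labels, values):
        mean_ranks[g] = ranks[start : start + len(v)].mean()
        sizes[g] = len(v)
        start += len(v)

    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        rows.append(
            {"group_1": g1, "group_2": g2, "z": z, "p": p, "p_adjusted": p_adj}
        )
    return pd.DataFrame(rows)


def chi_square_association(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    if isinstance(table, ContingencyTable):
        arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    result = stats.chi2_contingency(arr, correction=False)
    return float(result.statistic), float(result.pvalue)
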