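"""Voxel-wise two-group comparison: p-value heatmaps and cluster reports.

For a two-level phenotype split of the cohort (older/younger at the median
age, male/female, WHO grade I vs II+III, GTR vs STR, marker positive vs
negative, ...), every voxel yields a 2x2 table of tumour occupancy versus
group, tested with the two-tailed Fisher's exact test. Identical tables
repeat massively across voxels, so p values are computed once per distinct
(occupancy-A, occupancy-B) pair and broadcast back — millions of voxel
tests collapse to a few thousand distinct computations.

No multiple-testing correction is applied by default; Benjamini–Hochberg
adjusted q values are an opt-in extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .fisher import fisher_exact_two_tailed, voxel_contingency
from .io import Cohort, LesionMask, MARKERS, PatientRecord
from .synthetic import RegionAtlas

__all__ = [
    "PhenotypeSplit",
    "PValueMap",
    "compute_pvalue_map",
    "adjust_bh",
    "extract_significant_clusters",
    "split_by_threshold",
    "split_by_levels",
    "split_by_marker",
    "default_splits",
]


@dataclass
class PhenotypeSplit:
    """A rule dividing the cohort into groups A and B (or excluding)."""

    name: str
    assign: Callable[[PatientRecord], Optional[str]]

    def apply(self, cohort: Cohort) -> tuple[list[str], list[str], int]:
        """Return (group-A ids, group-B ids, number excluded)."""
        group_a, group_b, excluded = [], [], 0
        for r in cohort.records:
            g = self.assign(r)
            if g == "A":
                group_a.append(r.patient_id)
            elif g == "B":
                group_b.append(r.patient_id)
            else:
                excluded += 1
        return group_a, group_b, excluded


def split_by_threshold(field_name: str, cutoff: float, name=None) -> PhenotypeSplit:
    """A = records with ``field >= cutoff``, B = the rest (e.g. age >= 56)."""

    def assign(r: PatientRecord):
        value = getattr(r, field_name)
        if value is None:
            return None
        return "A" if value >= cutoff else "B"

    return PhenotypeSplit(name or f"{field_name}_ge_{cutoff:g}", assign)


def split_by_levels(field_name: str, a_levels, b_levels, name=None) -> PhenotypeSplit:
    a_levels, b_levels = set(a_levels), set(b_levels)

    def assign(r: PatientRecord):
        value = getattr(r, field_name)
        if value in a_levels:
            return "A"
        if value in b_levels:
            return "B"
        return None

    return PhenotypeSplit(name or field_name, assign)


def split_by_marker(marker: str) -> PhenotypeSplit:
    """A = marker positive, B = negative; missing excluded."""

    def assign(r: PatientRecord):
        value = r.markers.get(marker)
        if value is None:
            return None
        return "A" if value else "B"

    return PhenotypeSplit(marker, assign)


def default_splits(age_cutoff: float = 56.0) -> list[PhenotypeSplit]:
    """The standard comparison roster: age, sex, grade, EOR, recurrence, markers."""
    splits = [
        split_by_threshold("age", age_cutoff, name=f"age_ge_{age_cutoff:g}"),
        split_by_levels("sex", {"male"}, {"female"}, name="sex_male_vs_female"),
        split_by_levels("who_grade", {"II", "III"}, {"I"}, name="grade_II_III_vs_I"),
        split_by_levels("eor", {"GTR"}, {"STR"}, name="eor_gtr_vs_str"),
        split_by_levels("recurrence", {True}, {False}, name="recurrence_yes_vs_no"),
    ]
    splits += [split_by_marker(m) for m in MARKERS]
    return splits


@dataclass
class PValueMap:
    """Per-voxel two-tailed Fisher p values for one phenotype split."""

    p: np.ndarray  # in (0, 1]; 1 wherever untested
    tested: np.ndarray  # voxels with at least min_count lesions overall
    alpha: float
    split_name: str
    n_a: int
    n_b: int
    q: Optional[np.ndarray] = None  # BH-adjusted, tested voxels only
    n_distinct_tables: int = 0

    @property
    def significant(self) -> np.ndarray:
        sig = self.tested & (self.p < self.alpha)
        return sig

    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p, np.finfo(float).tiny))


def compute_pvalue_map(
    cohort: Cohort,
    masks: Mapping[str, LesionMask] | Sequence[LesionMask],
    split: PhenotypeSplit,
    min_count: int = 1,
    alpha: float = 0.05,
    fdr: bool = False,
) -> PValueMap:
    """Fisher's exact p at every voxel for one two-group split.

    Voxels where fewer than ``min_count`` patients (both groups pooled) have
    tumour are untested and assigned p = 1 — their table is degenerate and
    p = 1 analytically. With ``fdr=True`` a BH-adjusted q map is attached.
    """
    if isinstance(masks, Mapping):
        mask_by_id = dict(masks)
    else:
        mask_by_id = {m.patient_id: m for m in masks}

    ids_a, ids_b, _ = split.apply(cohort)
    ids_a = [i for i in ids_a if i in mask_by_id]
    ids_b = [i for i in ids_b if i in mask_by_id]
    if not ids_a or not ids_b:
        raise ValueError(f"split {split.name!r}: empty group (A={len(ids_a)}, B={len(ids_b)})")

    grid = next(iter(mask_by_id.values())).grid
    counts_a = np.zeros(grid.shape, dtype=np.int32)
    counts_b = np.zeros(grid.shape, dtype=np.int32)
    for i in ids_a:
        counts_a += mask_by_id[i].occupancy
    for i in ids_b:
        counts_b += mask_by_id[i].occupancy
    n_a, n_b = len(ids_a), len(ids_b)

    tested = (counts_a + counts_b) >= max(1, min_count)
    p = np.ones(grid.shape, dtype=float)

    # memoise per distinct (a, b) pair — n_a, n_b are constant over voxels
    ab = counts_a[tested].astype(np.int64) * (n_b + 1) + counts_b[tested]
    uniq, inverse = np.unique(ab, return_inverse=True)
    pvals = np.empty(len(uniq))
    for j, code in enumerate(uniq):
        a, b = int(code) // (n_b + 1), int(code) % (n_b + 1)
        pvals[j] = fisher_exact_two_tailed(voxel_contingency(a, n_a, b, n_b))
    p[tested] = pvals[inverse]

    pmap = PValueMap(
        p=p,
        tested=tested,
        alpha=alpha,
        split_name=split.name,
        n_a=n_a,
        n_b=n_b,
        n_distinct_tables=len(uniq),
    )
    if fdr:
        q = np.ones(grid.shape, dtype=float)
        q[tested] = adjust_bh(p[tested])
        pmap.q = q
    return pmap


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, each in [p, 1]."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


def extract_significant_clusters(
    pmap: PValueMap,
    atlas: Optional[RegionAtlas] = None,
    connectivity: int = 26,
    use_q: bool = False,
) -> pd.DataFrame:
    """Connected components of sub-alpha tested voxels.

    Returns one row per cluster — voxel count, peak -log10 p, world centroid,
    and its atlas category — sorted by size descending with deterministic
    tie-break on component id. A cluster is labelled by the category its
    voxels overlap most (clusters are usually much larger than the atlas
    seed regions, so a point lookup at the centroid would miss); a cluster
    overlapping no category falls back to the label at its centroid voxel,
    or "background".
    """
    if connectivity not in _CONNECTIVITY_ORDER:
        raise ValueError("connectivity must be 6, 18 or 26")
    values = pmap.q if use_q else pmap.p
    if values is None:
        raise ValueError("no q map attached; run compute_pvalue_map(fdr=True)")
    sig = pmap.tested & (values < pmap.alpha)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_ORDER[connectivity])
    labelled, n_clusters = ndimage.label(sig, structure=structure)

    grid = atlas.grid if atlas is not None else None
    rows = []
    neg_log = pmap.neg_log10_p()
    for cid in range(1, n_clusters + 1):
        voxels = np.argwhere(labelled == cid)
        centroid_vox = voxels.mean(axis=0)
        row = {
            "cluster_id": cid,
            "voxel_count": len(voxels),
            "peak_neg_log10_p": float(neg_log[labelled == cid].max()),
        }
        if grid is not None:
            world = grid.voxel_to_world(centroid_vox)
            row.update(
                centroid_x=float(world[0]),
                centroid_y=float(world[1]),
                centroid_z=float(world[2]),
            )
            overlap = atlas.labels[labelled == cid]
            overlap = overlap[overlap > 0]
            if overlap.size:
                ids, freqs = np.unique(overlap, return_counts=True)
                lbl = int(ids[np.argmax(freqs)])  # ties break on smaller id
            else:
                nearest = tuple(
                    np.clip(
                        np.round(centroid_vox).astype(int), 0, np.array(grid.shape) - 1
                    )
                )
                lbl = int(atlas.labels[nearest])
            row["atlas_category"] = atlas.names[lbl - 1] if lbl > 0 else "background"
        rows.append(row)

    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["voxel_count", "cluster_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
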