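"""Voxel-wise comparison maps, BH adjustment, and cluster extraction."""

import numpy as np
import pytest

from lesionmap.io import Cohort, LesionMask, PatientRecord
from lesionmap.voxelwise import (
    PValueMap,
    adjust_bh,
    compute_pvalue_map,
    default_splits,
    extract_significant_clusters,
    split_by_levels,
    split_by_threshold,
)


def _cohort_with_masks(grid, ages, voxels_per_patient):
    records, masks = [], {}
    for i, (age, voxels) in enumerate(zip(ages, voxels_per_patient)):
        pid = f"p{i}"
        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex="female",
                who_grade="I",
                location_label="falx",
            )
        )
        occ = np.zeros(grid.shape, dtype=bool)
        for v in voxels:
            occ[v] = True
        masks[pid] = LesionMask(pid, grid, occ)
    return Cohort(records=records, grid=grid), masks


def test_identical_membership_patterns_give_p_one(small_grid):
    # two equal-size groups whose members occupy identical voxel patterns
    voxels = [[(1, 1, 1)], [(2, 2, 2)], [(1, 1, 1)], [(2, 2, 2)]]
    cohort, masks = _cohort_with_masks(small_grid, [70, 70, 30, 30], voxels)
    pmap = compute_pvalue_map(cohort, masks, split_by_threshold("age", 56))
    assert np.all(pmap.p == 1.0)


def test_untested_voxels_get_p_one_and_tested_mask(small_grid):
    voxels = [[(0, 0, 0)], [(0, 0, 0)], [(4, 4, 4)], [(4, 4, 4)]]
    cohort, masks = _cohort_with_masks(small_grid, [70, 70, 30, 30], voxels)
    pmap = compute_pvalue_map(cohort, masks, split_by_threshold("age", 56), min_count=1)
    assert pmap.tested.sum() == 2
    assert np.all(pmap.p[~pmap.tested] == 1.0)
    # (2,0,0,2) table: two-tailed p = 2/C(4,2) = 1/3 at both voxels
    assert pmap.p[0, 0, 0] == pytest.approx(1.0 / 3.0)
    assert pmap.p[4, 4, 4] == pytest.approx(1.0 / 3.0)
    # the two voxels carry mirrored (a,b) pairs: two memoised entries
    assert pmap.n_distinct_tables == 2


def test_empty_group_raises_with_split_name(small_grid):
    voxels = [[(0, 0, 0)], [(1, 1, 1)]]
    cohort, masks = _cohort_with_masks(small_grid, [70, 71], voxels)
    with pytest.raises(ValueError, match="age_ge_56"):
        compute_pvalue_map(cohort, masks, split_by_threshold("age", 56))


def test_split_roster_and_exclusions():
    records = [
        PatientRecord(
            patient_id=f"r{i}",
            age=50 + i,
            sex="male" if i % 2 else "female",
            who_grade="I",
            location_label="falx",
            eor=None if i == 0 else "GTR",
            markers={"p53": None if i == 1 else True},
        )
        for i in range(4)
    ]
    cohort = Cohort(records=records)
    roster = {s.name: s for s in default_splits()}
    assert len(roster) == 10
    a, b, excluded = roster["eor_gtr_vs_str"].apply(cohort)
    assert len(a) == 3 and len(b) == 0 and excluded == 1  # missing EOR excluded
    a, b, excl = roster["p53"].apply(cohort)
    assert len(a) == 3 and len(b) == 0 and excl == 1  # missing marker excluded


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
        ((0.05,), (0.05,)),
        ((0.01, 0.04, 0.9), (0.03, 0.06, 0.9)),
    ],
)
def test_bh_step_up_worked_examples(pvals, expected):
    assert adjust_bh(np.array(pvals)) == pytest.approx(expected)


def test_bh_bounds_and_validation(rng):
    p = rng.uniform(size=200)
    q = adjust_bh(p)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
    with pytest.raises(ValueError):
        adjust_bh(np.array([0.5, 1.5]))


def _pmap_with_sig(grid, sig_voxels, alpha=0.05):
    p = np.ones(grid.shape)
    tested = np.zeros(grid.shape, dtype=bool)
    for v in sig_voxels:
        p[v] = 0.001
        tested[v] = True
    return PValueMap(
        p=p, tested=tested, alpha=alpha, split_name="t", n_a=1, n_b=1
    )


def test_cluster_connectivity_rules(grid):
    # two sub-alpha voxels sharing only a corner
    pmap = _pmap_with_sig(grid, [(10, 10, 10), (11, 11, 11)])
    six = extract_significant_clusters(pmap, connectivity=6)
    assert len(six) == 2
    twentysix = extract_significant_clusters(pmap, connectivity=26)
    assert len(twentysix) == 1
    assert twentysix["voxel_count"].iloc[0] == 2


def test_cluster_singleton_and_atlas_label(grid, atlas):
    # a lone significant voxel at the falx centroid
    inv = np.linalg.inv(grid.affine)
    centre = atlas.component_centroid("falx")
    vox = tuple(np.round(inv[:3, :3] @ centre + inv[:3, 3]).astype(int))
    pmap = _pmap_with_sig(grid, [vox])
    report = extract_significant_clusters(pmap, atlas)
    assert len(report) == 1
    assert report["voxel_count"].iloc[0] == 1
    assert report["atlas_category"].iloc[0] == "falx"
    assert report["peak_neg_log10_p"].iloc[0] == pytest.approx(3.0)


def test_empty_cluster_report_allowed(grid):
    pmap = _pmap_with_sig(grid, [])
    assert len(extract_significant_clusters(pmap)) == 0
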