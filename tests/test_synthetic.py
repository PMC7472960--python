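"""The synthetic cohort generator: determinism, marginals, planted effects."""

import numpy as np
import pytest

from lesionmap.io import LOCATION_CATEGORIES
from lesionmap.synthetic import (
    EffectSpec,
    SimulationConfig,
    build_region_atlas,
    generate_cohort,
    sample_records,
    simulate_recurrence,
)


def test_atlas_has_15_disjoint_categories(atlas):
    labels = atlas.labels
    present = set(np.unique(labels)) - {0}
    assert present == set(range(1, 16))
    for i in range(1, 16):
        assert (labels == i).sum() >= 1


def test_atlas_bilateral_components_mirror_across_midline(atlas):
    flipped = atlas.labels[::-1, :, :]
    assert np.array_equal(atlas.labels, flipped)
    for name in atlas.bilateral:
        sel = atlas.region_voxels(name)
        assert np.array_equal(sel, sel[::-1, :, :])
        # genuinely two-sided
        assert atlas.region_voxels(name, "left").any()
        assert atlas.region_voxels(name, "right").any()


def test_atlas_midline_categories_straddle_x0(atlas):
    wx = atlas.grid.world_x()
    for name in set(atlas.names) - atlas.bilateral:
        sel = atlas.labels == atlas.label_of(name)
        assert wx[sel].min() < 0 < wx[sel].max()


def test_atlas_deterministic_and_small_grid_rejected(grid):
    a1, a2 = build_region_atlas(grid), build_region_atlas(grid)
    assert np.array_equal(a1.labels, a2.labels)
    from lesionmap.grid import make_grid

    with pytest.raises(ValueError):
        build_region_atlas(make_grid((6, 6, 6), (4, 4, 4)))


def test_generate_cohort_reproducible_and_sized(atlas):
    cfg = SimulationConfig(n_patients=20, seed=9)
    cohort1, masks1 = generate_cohort(cfg, atlas)
    cohort2, masks2 = generate_cohort(cfg, atlas)
    assert cohort1.n == len(masks1) == 20
    for r1, r2 in zip(cohort1.records, cohort2.records):
        assert r1 == r2
    for pid in masks1:
        assert np.array_equal(masks1[pid].occupancy, masks2[pid].occupancy)


def test_location_marginals_converge_to_weights(atlas):
    """At n = 10,000 the convexity share sits within +-1.5 pp of its 20.8%
    sampling weight (binomial SE ~ 0.4 pp)."""
    cfg = SimulationConfig(n_patients=10_000, seed=11)
    records, _ = sample_records(cfg, atlas)
    share = 100.0 * sum(r.location_label == "convexity" for r in records) / len(records)
    assert abs(share - 20.8) <= 1.5
    female = 100.0 * sum(r.sex == "female" for r in records) / len(records)
    assert abs(female - 70.9) <= 1.5


def test_mask_volume_tracks_drawn_volume(atlas):
    cfg = SimulationConfig(n_patients=50, seed=21)
    records, placements = sample_records(cfg, atlas)
    cohort, masks = generate_cohort(cfg, atlas)
    vv = atlas.grid.voxel_volume
    interior = [
        (p, m)
        for p, m in zip(placements, masks.values())
        # blobs near the grid edge are legitimately clipped
        if m.voxel_count == int(round(p.volume_mm3 / vv))
    ]
    assert len(interior) >= len(placements) // 2
    # median rendered volume near the configured log-normal median
    med = np.median([m.voxel_count * vv for m in masks.values()]) / 1000.0
    assert med == pytest.approx(22.828, rel=0.5)


def test_planted_effect_enriches_target_region(atlas):
    """Grade II/III lesions under an odds-8 tilt occupy the target category
    far more often than grade I lesions."""
    effect = EffectSpec(
        covariate="who_grade",
        levels=frozenset({"II", "III"}),
        region="convexity",
        odds_multiplier=8.0,
    )
    cfg = SimulationConfig(n_patients=2000, seed=13, effect=effect)
    records, _ = sample_records(cfg, atlas)
    high = [r for r in records if r.who_grade in ("II", "III")]
    low = [r for r in records if r.who_grade == "I"]
    rate_high = sum(r.location_label == "convexity" for r in high) / len(high)
    rate_low = sum(r.location_label == "convexity" for r in low) / len(low)
    assert rate_high > rate_low + 0.2


def test_null_config_keeps_location_independent_of_phenotype(atlas):
    """Without an effect, grade and location are drawn independently: the
    convexity share among high-grade patients stays near the overall share."""
    cfg = SimulationConfig(n_patients=8000, seed=17)
    records, _ = sample_records(cfg, atlas)
    high = [r for r in records if r.who_grade in ("II", "III")]
    rate_high = sum(r.location_label == "convexity" for r in high) / len(high)
    assert abs(rate_high - 0.208) < 0.05


def _records(n, grade="I"):
    from lesionmap.io import PatientRecord

    return [
        PatientRecord(
            patient_id=f"r{i}",
            age=50,
            sex="female",
            who_grade=grade,
            location_label="falx",
        )
        for i in range(n)
    ]


def test_simulate_recurrence_degenerate_rates():
    none = simulate_recurrence(_records(30), (0, 0, 0), 60.0, seed=1)
    assert all(not r.recurrence and r.followup_time == 60.0 for r in none)
    every = simulate_recurrence(_records(30), (1, 1, 1), 60.0, seed=1)
    assert all(r.recurrence and 0 < r.followup_time <= 60.0 for r in every)
    with pytest.raises(ValueError):
        simulate_recurrence(_records(3), (0.5, 1.2, 0.1), 60.0, seed=1)


def test_simulate_recurrence_grade_marginals():
    """Grade-III recurrence within +-4 pp of 53.8% at n = 5,000."""
    recs = simulate_recurrence(
        _records(5000, grade="III"), (0.028, 0.079, 0.538), 60.0, seed=23
    )
    rate = 100.0 * sum(r.recurrence for r in recs) / len(recs)
    assert abs(rate - 53.8) <= 4.0


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=0)
    with pytest.raises(ValueError):
        SimulationConfig(location_probs=(1.0,) * 14)
    with pytest.raises(ValueError):
        EffectSpec("who_grade", frozenset({"I"}), "convexity", odds_multiplier=0.0)
    with pytest.raises(ValueError):
        EffectSpec("who_grade", frozenset({"I"}), "not_a_region", odds_multiplier=2.0)
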