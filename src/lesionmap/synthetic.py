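"""Synthetic meningioma cohorts on the template grid.

Generates desk-scale cohorts whose marginal structure mimics a large
single-centre surgical meningioma series: 15 dural location categories with
published frequencies, log-normal lesion volumes around the published
median, a 3:7 male:female ratio, WHO grade shares of roughly 90/9/1%, and
grade-dependent recurrence rates (2.8 / 7.9 / 53.8%). Lesions are rendered
as solid spheres of the drawn volume centred near category-specific
template coordinates, with a fair-coin hemisphere choice for bilateral
categories. An optional :class:`EffectSpec` plants a regional enrichment of
one phenotype so that planted-effect recovery of the voxel-wise comparison
can be measured; without it, phenotype labels are independent of lesion
location by construction, which is the basis of type-I calibration tests.

Each patient draws from an independent random stream derived from
``(seed, patient index)``, so generation is reproducible and insensitive
to iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .grid import TemplateGrid
from .io import Cohort, LesionMask, LOCATION_CATEGORIES, MARKERS, PatientRecord
from . import reference

__all__ = [
    "RegionAtlas",
    "EffectSpec",
    "SimulationConfig",
    "build_region_atlas",
    "generate_cohort",
    "sample_records",
    "render_mask",
    "simulate_recurrence",
]

#: seed-sphere radius (mm) of each atlas category component
ATLAS_RADIUS_MM = 6.0

# Template-like world coordinates (mm, RAS+) of each category's seed;
# bilateral categories get mirrored components at +-x.
_REGION_SPECS: dict[str, tuple[tuple[float, float, float], bool]] = {
    "convexity": ((45.0, 10.0, 55.0), True),
    "parasagittal_sinus": ((0.0, 10.0, 65.0), False),
    "falx": ((0.0, -20.0, 45.0), False),
    "tentorium": ((35.0, -55.0, 5.0), True),
    "cerebellar_convexity": ((30.0, -70.0, -30.0), True),
    "cerebellopontine_angle": ((40.0, -40.0, -35.0), True),
    "sphenoid_wing": ((45.0, 15.0, -5.0), True),
    "parasellar_cavernous_sinus": ((18.0, 5.0, -20.0), True),
    "tuberculum_sellae": ((0.0, 20.0, -10.0), False),
    "middle_fossa": ((40.0, -15.0, -25.0), True),
    "olfactory_groove": ((0.0, 35.0, -15.0), False),
    "clival_petroclival": ((0.0, -30.0, -35.0), False),
    "foramen_magnum": ((0.0, -40.0, -50.0), False),
    "intraventricular": ((25.0, -35.0, 20.0), True),
    "others": ((0.0, 55.0, 25.0), False),
}


@dataclass(frozen=True)
class RegionAtlas:
    """Deterministic 15-category label field over the template grid."""

    grid: TemplateGrid
    labels: np.ndarray  # int array, 0 = background, 1..15 = categories
    names: tuple[str, ...]
    centroids: dict[str, tuple[float, float, float]]
    bilateral: frozenset[str]

    def label_of(self, name: str) -> int:
        return self.names.index(name) + 1

    def component_centroid(
        self, name: str, side: Optional[str] = None
    ) -> np.ndarray:
        """World centroid of one category component (``side`` for bilateral)."""
        x, y, z = self.centroids[name]
        if name in self.bilateral:
            if side == "left":
                x = -abs(x)
            elif side == "right":
                x = abs(x)
            else:
                raise ValueError(f"{name} is bilateral; side required")
        return np.array([x, y, z])

    def region_voxels(self, name: str, side: Optional[str] = None) -> np.ndarray:
        """Boolean field of a category (optionally restricted to one side)."""
        sel = self.labels == self.label_of(name)
        if side is not None:
            wx = self.grid.world_x()
            sel &= (wx < 0) if side == "left" else (wx > 0)
        return sel


def build_region_atlas(grid: TemplateGrid) -> RegionAtlas:
    """Place the 15 disjoint category seed spheres on ``grid``.

    Bilateral categories receive mirrored components across the mid-sagittal
    plane; midline categories straddle x = 0. Raises if the grid cannot hold
    all spheres disjointly.
    """
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    labels = np.zeros(grid.n_voxels, dtype=np.int16)
    centroids: dict[str, tuple[float, float, float]] = {}
    bilateral = set()

    for i, name in enumerate(LOCATION_CATEGORIES, start=1):
        (x, y, z), is_bilateral = _REGION_SPECS[name]
        centroids[name] = (x, y, z)
        centres = [(x, y, z)]
        if is_bilateral:
            bilateral.add(name)
            centres = [(x, y, z), (-x, y, z)]
        for cx, cy, cz in centres:
            d2 = ((world - np.array([cx, cy, cz])) ** 2).sum(axis=1)
            sel = d2 <= ATLAS_RADIUS_MM**2
            if not sel.any():
                raise ValueError(
                    f"grid too small: category {name!r} has no voxels"
                )
            if (labels[sel] != 0).any():
                raise ValueError(
                    f"grid too small: category {name!r} overlaps another"
                )
            labels[sel] = i

    return RegionAtlas(
        grid=grid,
        labels=labels.reshape(grid.shape),
        names=LOCATION_CATEGORIES,
        centroids=centroids,
        bilateral=frozenset(bilateral),
    )


@dataclass(frozen=True)
class EffectSpec:
    """Planted regional enrichment of one categorical phenotype.

    Patients whose ``covariate`` value lies in ``levels`` have their
    location-category odds for ``region`` multiplied by ``odds_multiplier``
    (and, if ``side`` is set, their hemisphere odds tilted toward that side
    by the same factor). ``covariate`` is a record field (``who_grade``,
    ``sex``) or a marker name.
    """

    covariate: str
    levels: frozenset
    region: str
    odds_multiplier: float
    side: Optional[str] = None

    def __post_init__(self) -> None:
        if self.odds_multiplier <= 0:
            raise ValueError("odds_multiplier must be > 0")
        if self.region not in LOCATION_CATEGORIES:
            raise ValueError(f"unknown region {self.region!r}")

    def applies(self, record: PatientRecord) -> bool:
        if self.covariate in MARKERS:
            return record.markers.get(self.covariate) in self.levels
        return getattr(record, self.covariate) in self.levels


def _default_location_probs() -> tuple[float, ...]:
    total = sum(reference.LOCATION_COUNTS.values())
    return tuple(reference.LOCATION_COUNTS[c] / total for c in LOCATION_CATEGORIES)


def _default_marker_probs() -> dict[str, float]:
    # positivity rates: plausible clinical values; the source cohort does not
    # publish marker marginals
    return {"p53": 0.35, "ki67_gt5pct": 0.25, "ema": 0.85, "pr": 0.65, "cd34": 0.55}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort (defaults = the reference series)."""

    n_patients: int = 200
    seed: int = 0
    location_probs: tuple[float, ...] = field(default_factory=_default_location_probs)
    volume_log_mean: float = math.log(1000.0 * reference.MEDIAN_VOLUME_CM3)
    volume_log_sd: float = 0.8
    grade_probs: tuple[float, float, float] = (993 / 1107, 101 / 1107, 13 / 1107)
    sex_female_prob: float = 785 / 1107
    age_mean: float = 56.0
    age_sd: float = 13.0
    recurrence_rate_by_grade: tuple[float, float, float] = (0.028, 0.079, 0.538)
    followup_horizon: float = 60.0  # months
    eor_missing_prob: float = 57 / 1107
    eor_gtr_prob: float = 945 / 1050
    marker_pos_probs: dict[str, float] = field(default_factory=_default_marker_probs)
    effect: Optional[EffectSpec] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = np.asarray(self.location_probs, dtype=float)
        if probs.min() < 0 or probs.sum() <= 0 or len(probs) != len(LOCATION_CATEGORIES):
            raise ValueError("location_probs must be 15 nonnegative weights")
        object.__setattr__(self, "location_probs", tuple(probs / probs.sum()))
        gp = np.asarray(self.grade_probs, dtype=float)
        object.__setattr__(self, "grade_probs", tuple(gp / gp.sum()))
        for r in self.recurrence_rate_by_grade:
            if not 0.0 <= r <= 1.0:
                raise ValueError("recurrence rates must lie in [0, 1]")


class Placement(NamedTuple):
    """Where one synthetic lesion goes and how big it is."""

    category: str
    side: Optional[str]
    volume_mm3: float


_GRADES = ("I", "II", "III")


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def sample_records(
    config: SimulationConfig, atlas: RegionAtlas
) -> tuple[list[PatientRecord], list[Placement]]:
    """Draw covariates and lesion placements (no mask rendering).

    Covariates are drawn first; the location category is then drawn from
    the configured weights, tilted by the effect's odds multiplier when the
    patient carries the effect phenotype. Bilateral categories toss a fair
    coin for the hemisphere unless the effect targets one side.
    """
    records: list[PatientRecord] = []
    placements: list[Placement] = []
    effect = config.effect
    base_probs = np.asarray(config.location_probs)

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 13.0, 85.0))
        sex = "female" if rng.random() < config.sex_female_prob else "male"
        grade = _GRADES[rng.choice(3, p=config.grade_probs)]
        markers = {
            m: bool(rng.random() < p) for m, p in config.marker_pos_probs.items()
        }
        if rng.random() < config.eor_missing_prob:
            eor = None
        else:
            eor = "GTR" if rng.random() < config.eor_gtr_prob else "STR"

        record = PatientRecord(
            patient_id=f"S{i:05d}",
            age=round(age, 1),
            sex=sex,
            who_grade=grade,
            location_label="convexity",  # placeholder until drawn below
            eor=eor,
            markers=markers,
        )

        probs = base_probs
        carries_effect = effect is not None and effect.applies(record)
        if carries_effect:
            probs = probs.copy()
            probs[LOCATION_CATEGORIES.index(effect.region)] *= effect.odds_multiplier
            probs = probs / probs.sum()
        category = LOCATION_CATEGORIES[rng.choice(len(probs), p=probs)]
        record.location_label = category

        side = None
        if category in atlas.bilateral:
            p_target = 0.5
            target = "right"
            if carries_effect and effect.side is not None and category == effect.region:
                target = effect.side
                p_target = effect.odds_multiplier / (effect.odds_multiplier + 1.0)
            side = target if rng.random() < p_target else (
                "left" if target == "right" else "right"
            )

        volume = float(rng.lognormal(config.volume_log_mean, config.volume_log_sd))
        max_volume = atlas.grid.n_voxels * atlas.grid.voxel_volume
        if volume > max_volume:
            raise ValueError(
                f"drawn volume {volume:.0f} mm^3 exceeds the grid ({max_volume:.0f})"
            )
        records.append(record)
        placements.append(Placement(category, side, volume))
    return records, placements


def render_mask(
    record_id: str,
    placement: Placement,
    atlas: RegionAtlas,
    rng: np.random.Generator,
) -> LesionMask:
    """Render one lesion: the k grid voxels nearest the jittered centre.

    k is the drawn volume divided by the voxel volume; the centre is the
    category-component centroid plus isotropic Gaussian jitter of one voxel.
    Blobs are clipped at the grid boundary. Ties in distance break on voxel
    index, so rendering is deterministic given the stream.
    """
    grid = atlas.grid
    spacing = np.asarray(grid.spacing)
    centre = atlas.component_centroid(
        placement.category, placement.side
    ) + rng.normal(0.0, 1.0, size=3) * spacing

    k = max(1, int(round(placement.volume_mm3 / grid.voxel_volume)))
    k = min(k, grid.n_voxels)
    radius = ((3.0 * k * grid.voxel_volume) / (4.0 * math.pi)) ** (1.0 / 3.0)
    pad = radius * 1.6 + 2.0 * spacing.max()

    # candidate bounding box in voxel indices, clipped to the grid
    inv = np.linalg.inv(grid.affine)
    centre_vox = (inv[:3, :3] @ centre + inv[:3, 3])
    lo = np.maximum(np.floor(centre_vox - pad / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(centre_vox + pad / spacing).astype(int) + 1, grid.shape)
    sub = np.stack(
        np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    d2 = ((grid.voxel_to_world(sub) - centre) ** 2).sum(axis=1)
    flat = np.ravel_multi_index(sub.T, grid.shape)
    order = np.lexsort((flat, d2))
    chosen = flat[order[: min(k, len(flat))]]

    occ = np.zeros(grid.n_voxels, dtype=bool)
    occ[chosen] = True
    return LesionMask(patient_id=record_id, grid=grid, occupancy=occ.reshape(grid.shape))


def simulate_recurrence(
    records: Sequence[PatientRecord],
    rates_by_grade: Sequence[float],
    followup_horizon: float,
    seed: int,
) -> list[PatientRecord]:
    """Draw recurrence outcomes and follow-up times, per WHO grade.

    Recurrence is Bernoulli with the grade's rate; recurrences get an event
    time uniform on (0, horizon], everyone else is censored at the horizon.
    Returns new records (inputs untouched).
    """
    rates = list(rates_by_grade)
    if len(rates) != 3 or any(not 0.0 <= r <= 1.0 for r in rates):
        raise ValueError("rates_by_grade must be 3 fractions in [0, 1]")
    out = []
    for i, r in enumerate(records):
        rng = _patient_rng(seed, i, stream=1)
        rate = rates[_GRADES.index(r.who_grade)]
        recur = bool(rng.random() < rate)
        time = (
            float(rng.uniform(0.0, followup_horizon)) if recur else followup_horizon
        )
        out.append(replace_record(r, recurrence=recur, followup_time=time))
    return out


def replace_record(record: PatientRecord, **changes) -> PatientRecord:
    d = dict(
        patient_id=record.patient_id,
        age=record.age,
        sex=record.sex,
        who_grade=record.who_grade,
        location_label=record.location_label,
        eor=record.eor,
        recurrence=record.recurrence,
        followup_time=record.followup_time,
        markers=dict(record.markers),
        mask_path=record.mask_path,
    )
    d.update(changes)
    return PatientRecord(**d)


def generate_cohort(
    config: SimulationConfig,
    atlas: RegionAtlas,
    make_masks: bool = True,
) -> tuple[Cohort, dict[str, LesionMask]]:
    """Full synthetic cohort: covariates, outcomes and (optionally) masks.

    Identical ``(config, seed)`` yield bit-identical cohorts and masks.
    ``make_masks=False`` skips rendering for analyses that only need the
    covariate table (large-n marginal checks, survival simulations).
    """
    records, placements = sample_records(config, atlas)
    records = simulate_recurrence(
        records, config.recurrence_rate_by_grade, config.followup_horizon, config.seed
    )
    masks: dict[str, LesionMask] = {}
    if make_masks:
        for i, (rec, plc) in enumerate(zip(records, placements)):
            rng = _patient_rng(config.seed, i, stream=2)
            masks[rec.patient_id] = render_mask(rec.patient_id, plc, atlas, rng)
    return Cohort(records=records, grid=atlas.grid), masks
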