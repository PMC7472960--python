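"""Cohort records, lesion masks, and NIfTI / CSV input-output.

A cohort is a table of patient covariates (age, sex, WHO grade, location
category, extent of resection, recurrence, follow-up, immunohistochemical
markers) plus one binary lesion mask per patient, all registered to the
shared :class:`~lesionmap.grid.TemplateGrid`. Missing covariates are kept
explicit (``None``) and excluded per-analysis rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridMismatchError, TemplateGrid

__all__ = [
    "LOCATION_CATEGORIES",
    "SKULL_BASE_CATEGORIES",
    "MARKERS",
    "LesionMask",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_mask_file",
    "write_mask_file",
    "write_map_file",
    "read_cohort_table",
    "write_cohort_table",
]

#: The 15 dural location categories used to classify intracranial meningiomas.
LOCATION_CATEGORIES: tuple[str, ...] = (
    "convexity",
    "parasagittal_sinus",
    "falx",
    "tentorium",
    "cerebellar_convexity",
    "cerebellopontine_angle",
    "sphenoid_wing",
    "parasellar_cavernous_sinus",
    "tuberculum_sellae",  # tuberculum sellae / planum sphenoidale / ant. clinoid
    "middle_fossa",
    "olfactory_groove",
    "clival_petroclival",
    "foramen_magnum",
    "intraventricular",
    "others",  # multiple / orbital / jugular foramen
)

#: The eight categories conventionally grouped as skull base.
SKULL_BASE_CATEGORIES: frozenset[str] = frozenset(
    {
        "cerebellopontine_angle",
        "sphenoid_wing",
        "parasellar_cavernous_sinus",
        "tuberculum_sellae",
        "middle_fossa",
        "olfactory_groove",
        "clival_petroclival",
        "foramen_magnum",
    }
)

#: Binary immunohistochemical markers carried per patient.
MARKERS: tuple[str, ...] = ("p53", "ki67_gt5pct", "ema", "pr", "cd34")


class CohortValidationError(ValueError):
    """The cohort table violates an invariant (duplicate ids, bad labels...)."""


@dataclass
class LesionMask:
    """Binary occupancy of one patient's lesion over the template grid."""

    patient_id: str
    grid: TemplateGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask {self.patient_id}: occupancy shape {occ.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        self.occupancy = occ

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str  # "male" | "female"
    who_grade: str  # "I" | "II" | "III"
    location_label: str
    eor: Optional[str] = None  # "GTR" | "STR" | None (missing)
    recurrence: Optional[bool] = None
    followup_time: float = 0.0  # months
    markers: dict[str, Optional[bool]] = field(default_factory=dict)
    mask_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CohortValidationError(f"{self.patient_id}: negative age")
        if self.followup_time < 0:
            raise CohortValidationError(f"{self.patient_id}: negative follow-up")
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"{self.patient_id}: bad sex {self.sex!r}")
        if self.who_grade not in ("I", "II", "III"):
            raise CohortValidationError(
                f"{self.patient_id}: bad WHO grade {self.who_grade!r}"
            )
        if self.eor not in ("GTR", "STR", None):
            raise CohortValidationError(f"{self.patient_id}: bad EOR {self.eor!r}")

    def marker(self, name: str) -> Optional[bool]:
        return self.markers.get(name)


@dataclass
class Cohort:
    records: list[PatientRecord]
    grid: Optional[TemplateGrid] = None

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")
        bad = sorted(
            {r.location_label for r in self.records}
            - set(LOCATION_CATEGORIES)
        )
        if bad:
            raise CohortValidationError(f"unknown location labels: {bad}")

    @property
    def n(self) -> int:
        return len(self.records)

    def eor_evaluable(self) -> list[PatientRecord]:
        """Records with a known extent of resection."""
        return [r for r in self.records if r.eor is not None]


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_mask_file(
    path, grid: TemplateGrid, threshold: float = 0.5
) -> LesionMask:
    """Load a NIfTI lesion mask, binarising values > ``threshold``.

    The stored geometry must match ``grid`` (shape exactly, affine within
    tolerance); the 0.5 default threshold is robust to interpolation blur
    from resampling a binary segmentation.
    """
    img = nib.load(str(path))
    grid.require_match(img.shape, img.affine, what=str(path))
    data = np.asanyarray(img.dataobj)
    return LesionMask(
        patient_id=Path(path).name.split(".")[0],
        grid=grid,
        occupancy=data > threshold,
    )


def write_mask_file(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def write_map_file(values: np.ndarray, grid: TemplateGrid, path) -> None:
    """Write a scalar map (counts, percentages, p values) over the grid.

    Integer arrays are stored as int32 and floats as float64 so a read-back
    reproduces the values bit-exactly.
    """
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"map shape {values.shape} != grid shape {grid.shape}"
        )
    dtype = np.int32 if values.dtype.kind in "biu" else np.float64
    img = nib.Nifti1Image(values.astype(dtype), grid.affine)
    nib.save(img, str(path))


def read_map_file(path, grid: TemplateGrid) -> np.ndarray:
    img = nib.load(str(path))
    grid.require_match(img.shape, img.affine, what=str(path))
    return np.asanyarray(img.dataobj)


# ---------------------------------------------------------------------------
# Cohort table I/O

_BOOL_IN = {"positive": True, "negative": False, "yes": True, "no": False}
_BOOL_OUT = {True: "positive", False: "negative", None: ""}
_REC_OUT = {True: "yes", False: "no", None: ""}


def _parse_optional(value, mapping: Mapping[str, object]):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    if s not in mapping:
        raise CohortValidationError(f"unparseable value {value!r}")
    return mapping[s]


def read_cohort_table(path, grid: Optional[TemplateGrid] = None) -> Cohort:
    """Load and validate a cohort covariate CSV.

    Expected header: ``patient_id, age, sex, who_grade, location_label,
    eor, recurrence, followup_time, p53, ki67_gt5pct, ema, pr, cd34,
    mask_path``. Empty cells denote missing values; records with missing
    EOR are retained (flagged ``eor=None``) and excluded only from
    EOR-stratified analyses.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "age", "sex", "who_grade", "location_label"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"missing columns: {sorted(missing_cols)}")

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        markers = {
            m: _parse_optional(d.get(m), _BOOL_IN) for m in MARKERS if m in d
        }
        eor = d.get("eor")
        eor = None if pd.isna(eor) or str(eor).strip() == "" else str(eor).strip()
        mask_path = d.get("mask_path")
        mask_path = (
            None
            if mask_path is None or pd.isna(mask_path) or str(mask_path) == ""
            else str(mask_path)
        )
        records.append(
            PatientRecord(
                patient_id=str(d["patient_id"]),
                age=float(d["age"]),
                sex=str(d["sex"]),
                who_grade=str(d["who_grade"]),
                location_label=str(d["location_label"]),
                eor=eor,
                recurrence=_parse_optional(d.get("recurrence"), _BOOL_IN),
                followup_time=float(d.get("followup_time", 0.0) or 0.0),
                markers=markers,
                mask_path=mask_path,
            )
        )
    return Cohort(records=records, grid=grid)


def write_cohort_table(cohort: Cohort, path) -> None:
    rows = []
    for r in cohort.records:
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "who_grade": r.who_grade,
            "location_label": r.location_label,
            "eor": r.eor or "",
            "recurrence": _REC_OUT[r.recurrence],
            "followup_time": r.followup_time,
        }
        for m in MARKERS:
            row[m] = _BOOL_OUT[r.markers.get(m)]
        row["mask_path"] = r.mask_path or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_masks(
    cohort: Cohort, grid: TemplateGrid, base_dir=None, threshold: float = 0.5
) -> dict[str, LesionMask]:
    """Read every record's ``mask_path`` relative to ``base_dir``."""
    masks: dict[str, LesionMask] = {}
    base = Path(base_dir) if base_dir is not None else Path(".")
    for r in cohort.records:
        if r.mask_path is None:
            continue
        mask = read_mask_file(base / r.mask_path, grid, threshold=threshold)
        mask.patient_id = r.patient_id
        masks[r.patient_id] = mask
    return masks
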