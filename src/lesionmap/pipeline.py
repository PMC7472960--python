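"""End-to-end orchestration: config -> cohort -> maps, tables and report.

A single flat configuration drives the whole analysis: load a real cohort
(covariate CSV plus NIfTI masks in template space) or simulate a synthetic
one, build the frequency heatmap and location summary, run every configured
phenotype split through the voxel-wise Fisher comparison, compute volumes,
laterality and recurrence-free survival, and write a stable file layout of
NIfTI maps and CSV tables. A failure in one split is logged and does not
abort the others; identical (config, seed) reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frequency import build_frequency_map, location_summary
from .grid import make_grid
from .io import (
    SKULL_BASE_CATEGORIES,
    Cohort,
    load_masks,
    read_cohort_table,
    write_cohort_table,
    write_map_file,
    write_mask_file,
)
from .laterality import laterality_table
from .survival import rfs_comparison, standard_rules
from .synthetic import EffectSpec, SimulationConfig, build_region_atlas, generate_cohort
from .volume import dunn_posthoc, kruskal_wallis_test, volume_table
from .voxelwise import compute_pvalue_map, default_splits, extract_significant_clusters

__all__ = ["PipelineConfig", "ReportBundle", "load_config", "run_pipeline", "write_report"]

DEFAULT_GRID_SHAPE = (45, 54, 45)
DEFAULT_GRID_SPACING = (4.0, 4.0, 4.0)


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "real"
    seed: int = 0
    n_patients: int = 200
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    grid_spacing: tuple[float, float, float] = DEFAULT_GRID_SPACING
    voxel_volume_override: Optional[float] = None
    cohort_csv: Optional[str] = None
    masks_dir: Optional[str] = None
    splits: str = "all"  # "all" or comma-separated split names
    alpha: float = 0.05
    min_count: int = 1
    connectivity: int = 26
    fdr: bool = False
    age_cutoff: float = 56.0
    volume_cutoff_cm3: float = 22.828
    followup_horizon: float = 60.0
    effect_covariate: Optional[str] = None
    effect_levels: Optional[list] = None
    effect_region: Optional[str] = None
    effect_side: Optional[str] = None
    effect_odds: float = 1.0
    enable_frequency: bool = True
    enable_comparisons: bool = True
    enable_volumes: bool = True
    enable_laterality: bool = True
    enable_survival: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real" and not self.cohort_csv:
            raise ValueError("real mode requires cohort_csv")
        if not any(
            [
                self.enable_frequency,
                self.enable_comparisons,
                self.enable_volumes,
                self.enable_laterality,
                self.enable_survival,
            ]
        ):
            raise ValueError("no analysis enabled")

    def effect_spec(self) -> Optional[EffectSpec]:
        if not self.effect_region:
            return None
        return EffectSpec(
            covariate=self.effect_covariate,
            levels=frozenset(self.effect_levels or ()),
            region=self.effect_region,
            odds_multiplier=self.effect_odds,
            side=self.effect_side,
        )

    def to_flat_dict(self) -> dict:
        d = {}
        for key, value in self.__dict__.items():
            if isinstance(value, tuple):
                value = list(value)
            d[key] = value
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read the flat key-value (YAML) pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("grid_shape", "grid_spacing"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


@dataclass
class ReportBundle:
    config: PipelineConfig
    grid: object
    atlas: object
    cohort: Cohort
    masks: dict
    frequency_map: object = None
    location_summary: Optional[pd.DataFrame] = None
    pvalue_maps: dict = field(default_factory=dict)
    cluster_reports: dict = field(default_factory=dict)
    volume_table: Optional[pd.DataFrame] = None
    volume_comparisons: dict = field(default_factory=dict)
    laterality: Optional[pd.DataFrame] = None
    survival: Optional[pd.DataFrame] = None
    errors: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    memo_tables: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    grid = make_grid(
        config.grid_shape, config.grid_spacing, config.voxel_volume_override
    )
    atlas = build_region_atlas(grid)
    if config.mode == "synthetic":
        sim = SimulationConfig(
            n_patients=config.n_patients,
            seed=config.seed,
            followup_horizon=config.followup_horizon,
            effect=config.effect_spec(),
        )
        cohort, masks = generate_cohort(sim, atlas)
    else:
        cohort = read_cohort_table(config.cohort_csv, grid)
        masks = load_masks(cohort, grid, base_dir=config.masks_dir)
    return grid, atlas, cohort, masks


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every enabled stage in fixed order; isolate per-split failures."""
    t0 = time.perf_counter()
    grid, atlas, cohort, masks = _load_inputs(config)
    bundle = ReportBundle(config=config, grid=grid, atlas=atlas, cohort=cohort, masks=masks)
    bundle.timings["load"] = time.perf_counter() - t0

    if config.enable_frequency:
        t = time.perf_counter()
        bundle.frequency_map = build_frequency_map(list(masks.values()), cohort.n)
        bundle.location_summary = location_summary(cohort)
        bundle.timings["frequency"] = time.perf_counter() - t

    if config.enable_comparisons:
        t = time.perf_counter()
        roster = default_splits(age_cutoff=config.age_cutoff)
        if config.splits != "all":
            wanted = {s.strip() for s in config.splits.split(",")}
            roster = [s for s in roster if s.name in wanted]
        for split in roster:
            try:
                pmap = compute_pvalue_map(
                    cohort,
                    masks,
                    split,
                    min_count=config.min_count,
                    alpha=config.alpha,
                    fdr=config.fdr,
                )
                bundle.pvalue_maps[split.name] = pmap
                bundle.cluster_reports[split.name] = extract_significant_clusters(
                    pmap, atlas, connectivity=config.connectivity
                )
                bundle.memo_tables[split.name] = pmap.n_distinct_tables
            except ValueError as exc:
                bundle.errors[split.name] = str(exc)
        bundle.timings["comparisons"] = time.perf_counter() - t

    volumes_cm3 = {}
    if config.enable_volumes or config.enable_survival:
        locations = {r.patient_id: r.location_label for r in cohort.records}
        bundle.volume_table = volume_table(masks, locations, grid)
        volumes_cm3 = dict(
            zip(bundle.volume_table["patient_id"], bundle.volume_table["volume_cm3"])
        )

    if config.enable_volumes and len(volumes_cm3):
        t = time.perf_counter()
        df = bundle.volume_table
        skull = df[df["location_label"].isin(SKULL_BASE_CATEGORIES)]
        non_skull = df[~df["location_label"].isin(SKULL_BASE_CATEGORIES)]
        try:
            groups = {
                "skull_base": skull["volume_cm3"].tolist(),
                "non_skull_base": non_skull["volume_cm3"].tolist(),
            }
            h, p = kruskal_wallis_test(groups)
            bundle.volume_comparisons["skull_vs_non_skull"] = {"H": h, "p": p}
        except ValueError as exc:
            bundle.errors["skull_vs_non_skull"] = str(exc)
        sb_groups = {
            cat: grp["volume_cm3"].tolist()
            for cat, grp in skull.groupby("location_label")
            if len(grp) >= 2
        }
        if len(sb_groups) >= 3:
            try:
                h, p = kruskal_wallis_test(sb_groups)
                bundle.volume_comparisons["skull_base_categories"] = {
                    "H": h,
                    "p": p,
                    "posthoc": dunn_posthoc(sb_groups),
                }
            except ValueError as exc:
                bundle.errors["skull_base_categories"] = str(exc)
        bundle.timings["volumes"] = time.perf_counter() - t

    if config.enable_laterality and masks:
        t = time.perf_counter()
        bundle.laterality = laterality_table(cohort, masks)
        bundle.timings["laterality"] = time.perf_counter() - t

    if config.enable_survival:
        t = time.perf_counter()
        rows = []
        for rule in standard_rules(config.age_cutoff, config.volume_cutoff_cm3):
            res = rfs_comparison(cohort, rule, extra=volumes_cm3 if "volume" in rule.covariate else None)
            rows.append(
                {
                    "rule": res["rule"],
                    "n_a": res["n_a"],
                    "n_b": res["n_b"],
                    "n_excluded": res["n_excluded"],
                    "logrank_statistic": res.get("statistic", float("nan")),
                    "p": res.get("p", float("nan")),
                    "error": res.get("error", ""),
                }
            )
        bundle.survival = pd.DataFrame(rows)
        bundle.timings["survival"] = time.perf_counter() - t

    bundle.timings["total"] = time.perf_counter() - t0
    return bundle


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write maps/, tables/ and log.txt under ``outdir``."""
    outdir = Path(outdir)
    maps_dir = outdir / "maps"
    tables_dir = outdir / "tables"
    maps_dir.mkdir(parents=True, exist_ok=True)
    tables_dir.mkdir(parents=True, exist_ok=True)
    grid = bundle.grid

    if bundle.frequency_map is not None:
        write_map_file(bundle.frequency_map.counts, grid, maps_dir / "frequency_counts.nii.gz")
        write_map_file(bundle.frequency_map.percentage, grid, maps_dir / "frequency_percent.nii.gz")
    if bundle.location_summary is not None:
        bundle.location_summary.to_csv(tables_dir / "location_summary.csv", index=False)

    for name, pmap in bundle.pvalue_maps.items():
        write_map_file(pmap.p, grid, maps_dir / f"p_{name}.nii.gz")
        if pmap.q is not None:
            write_map_file(pmap.q, grid, maps_dir / f"q_{name}.nii.gz")
        report = bundle.cluster_reports.get(name)
        if report is not None:
            report.to_csv(tables_dir / f"clusters_{name}.csv", index=False)

    if bundle.volume_table is not None:
        bundle.volume_table.to_csv(tables_dir / "volumes.csv", index=False)
    if bundle.volume_comparisons:
        rows = []
        for name, res in bundle.volume_comparisons.items():
            rows.append({"comparison": name, "H": res["H"], "p": res["p"]})
            if "posthoc" in res:
                res["posthoc"].to_csv(tables_dir / f"dunn_{name}.csv", index=False)
        pd.DataFrame(rows).to_csv(tables_dir / "volume_comparisons.csv", index=False)
    if bundle.laterality is not None:
        bundle.laterality.to_csv(tables_dir / "laterality.csv", index=False)
    if bundle.survival is not None:
        bundle.survival.to_csv(tables_dir / "survival.csv", index=False)

    log = {
        "lesionmap_version": __version__,
        "config_hash": bundle.config.hash(),
        "config": bundle.config.to_flat_dict(),
        "timings_s": {k: round(v, 3) for k, v in bundle.timings.items()},
        "distinct_fisher_tables": bundle.memo_tables,
        "errors": bundle.errors,
        "n_patients": bundle.cohort.n,
    }
    (outdir / "log.txt").write_text(json.dumps(log, indent=2, sort_keys=True))


def simulate_to_disk(config: PipelineConfig, outdir) -> None:
    """Materialise a synthetic cohort as the CSV + NIfTI layout the
    pipeline's real mode reads back."""
    outdir = Path(outdir)
    masks_dir = outdir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    grid, atlas, cohort, masks = _load_inputs(config)
    for r in cohort.records:
        rel = f"masks/{r.patient_id}.nii.gz"
        write_mask_file(masks[r.patient_id], outdir / rel)
        r.mask_path = rel
    write_cohort_table(cohort, outdir / "cohort.csv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=True)
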