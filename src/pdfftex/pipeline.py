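"""Orchestration: simulate -> extract -> stats as one reproducible run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ALL_FEATURES, MUSCLES, SIDES, __version__
from .cohort_stats import run_paper_statistics
from .glcm_texture import (DEFAULT_NG, bilateral_aggregate, build_glcm,
                           glcm_features, glcm_features_per_direction, quantize)
from .global_texture import global_features
from .synthetic_cohort import CohortSpec, EffectModel, default_effect_models, generate_cohort
from .volume_io import (PDFFVolume, ROIMask, load_covariates, load_mask,
                        load_volume, read_manifest, roi_values, roi_volume_mm3,
                        save_mask, save_volume, write_manifest)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    out_dir: str = "pdfftex_run"
    input_dir: str | None = None  # None -> simulate
    ng: int = DEFAULT_NG
    distance_correction: bool = True
    aggregation: str = "single-matrix"  # or 'per-direction'
    use_raw_moments: bool = False
    by_sex: bool = True
    fdr: bool = False
    correlation_method: str = "pearson"
    master_seed: int = 0
    n_male: int = 25
    n_female: int = 54
    grid_shape: tuple[int, int, int] = (32, 32, 10)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    slices_per_roi: int = 10
    correlation_length: float = 1.5
    effect_models: dict | None = None  # per-muscle EffectModel overrides
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size"] = list(self.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        if "voxel_size" in d:
            d["voxel_size"] = tuple(float(v) for v in d["voxel_size"])
        return cls(**d)

    def cohort_spec(self) -> CohortSpec:
        models = default_effect_models()
        if self.effect_models:
            for muscle, overrides in self.effect_models.items():
                base = asdict(models[muscle])
                base.update(overrides)
                models[muscle] = EffectModel(**base)
        return CohortSpec(
            n_male=self.n_male, n_female=self.n_female, effect_models=models,
            grid_shape=self.grid_shape, voxel_size=self.voxel_size,
            slices_per_roi=self.slices_per_roi,
            correlation_length=self.correlation_length,
            master_seed=self.master_seed,
        )


def extract_subject_features(volume: PDFFVolume,
                             masks: dict[tuple[str, str], ROIMask],
                             ng: int = DEFAULT_NG,
                             distance_correction: bool = True,
                             aggregation: str = "single-matrix",
                             use_raw_moments: bool = False) -> dict[str, dict[str, float]]:
    """Bilateral feature vector per muscle for one subject (in memory).

    Per side: mean PDFF + 3 global features + 8 GLCM features; sides are
    then volume-weighted into one vector per muscle. Muscles with no mask
    on either side are omitted.
    """
    out: dict[str, dict[str, float]] = {}
    for muscle in MUSCLES:
        sides: dict[str, tuple[dict[str, float], float]] = {}
        for side in SIDES:
            roi = masks.get((muscle, side))
            if roi is None or not roi.mask.any():
                continue
            vals = roi_values(volume, roi)
            feats = global_features(vals, use_raw_moments=use_raw_moments).as_dict()
            q = quantize(volume.values, roi.mask, ng=ng)
            if aggregation == "per-direction":
                gf = glcm_features_per_direction(q, volume.voxel_size,
                                                 distance_correction)
            else:
                gf = glcm_features(build_glcm(q, volume.voxel_size,
                                              distance_correction))
            feats.update(gf.as_dict())
            sides[side] = (feats, roi_volume_mm3(roi, volume.voxel_size))
        if not sides:
            continue
        left = sides.get("left", ({}, 0.0))
        right = sides.get("right", ({}, 0.0))
        out[muscle] = bilateral_aggregate(left[0], right[0], left[1], right[1])
    return out


def features_to_row(subject_id: str, per_muscle: dict[str, dict[str, float]]) -> dict:
    row: dict[str, float | str] = {"subject_id": subject_id}
    for muscle, feats in per_muscle.items():
        for name in ALL_FEATURES:
            row[f"{name}_{muscle}"] = feats.get(name, float("nan"))
    return row


def run_simulate(config: RunConfig, out_dir: Path) -> dict:
    """Generate the synthetic cohort and write NIfTI/CSV/JSON artifacts."""
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    subjects, masks, covariates = generate_cohort(spec)

    mask_paths: dict[str, str] = {}
    for (muscle, side), roi in sorted(masks.items()):
        p = out_dir / f"mask_{muscle}_{side}.nii.gz"
        save_mask(roi, spec.voxel_size, p)
        mask_paths[f"{muscle}_{side}"] = p.name

    records = []
    for sspec, volume in subjects:
        p = out_dir / f"{sspec.subject_id}_pdff.nii.gz"
        save_volume(volume, p)
        records.append({"subject_id": sspec.subject_id, "volume": p.name,
                        "seed": sspec.seed})
    covariates.to_csv(out_dir / "covariates.csv", index=False)
    manifest = {
        "masks": mask_paths,
        "subjects": records,
        "covariates": "covariates.csv",
        "master_seed": spec.master_seed,
    }
    write_manifest(manifest, out_dir / "cohort_manifest.json")
    return manifest


def run_extract(config: RunConfig, input_dir: Path, out_path: Path) -> pd.DataFrame:
    """Extract the bilateral feature table for a simulated/real cohort on disk.

    Per-subject failures are logged and skipped; zero successfully
    processed subjects is fatal.
    """
    manifest = read_manifest(input_dir / "cohort_manifest.json")
    covariates = load_covariates(input_dir / manifest["covariates"])

    rows = []
    n_failed = 0
    for rec in manifest["subjects"]:
        sid = rec["subject_id"]
        try:
            volume = load_volume(input_dir / rec["volume"])
            masks: dict[tuple[str, str], ROIMask] = {}
            for key, fname in manifest["masks"].items():
                muscle, side = key.rsplit("_", 1)
                mask_file = input_dir / fname
                if not mask_file.exists():
                    logger.warning("subject %s: missing mask %s, skipping ROI", sid, fname)
                    continue
                masks[(muscle, side)] = load_mask(mask_file, muscle, side, volume)
            per_muscle = extract_subject_features(
                volume, masks, ng=config.ng,
                distance_correction=config.distance_correction,
                aggregation=config.aggregation,
                use_raw_moments=config.use_raw_moments)
            if not per_muscle:
                raise ValueError("no usable ROI")
            rows.append(features_to_row(sid, per_muscle))
        except Exception:
            n_failed += 1
            logger.exception("subject %s failed, skipped", sid)
    if not rows:
        raise RuntimeError("extraction failed for every subject")
    if n_failed:
        logger.warning("%d subject(s) skipped during extraction", n_failed)
    features = pd.DataFrame(rows)
    table = covariates.merge(features, on="subject_id", how="inner")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    return table


def run_stats(config: RunConfig, table: pd.DataFrame, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    results = run_paper_statistics(table, by_sex=config.by_sex, fdr=config.fdr,
                                   method=config.correlation_method)
    paths = {}
    for name, df in results.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute simulate (if no input dir), extract, and stats; write a manifest."""
    out_dir = Path(config.out_dir)
    if not config.out_dir:
        raise ValueError("output directory must be set before any compute")
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.input_dir is None:
            data_dir = out_dir / "data"
            run_simulate(config, data_dir)
        else:
            data_dir = Path(config.input_dir)
        stage = "extract"
        features_path = out_dir / "features.csv"
        table = run_extract(config, data_dir, features_path)
        stage = "stats"
        stats_paths = run_stats(config, table, out_dir / "stats")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    outputs = {"features": features_path, **stats_paths}
    manifest = {
        "config": config.as_dict(),
        "version": __version__,
        "master_seed": config.master_seed,
        "n_subjects": int(len(table)),
        "outputs": {k: str(p.relative_to(out_dir)) for k, p in outputs.items()},
        "hashes": {k: _sha256(p) for k, p in outputs.items()},
    }
    write_manifest(manifest, out_dir / "run_manifest.json")
    return manifest


def cohort_feature_table(config: RunConfig) -> pd.DataFrame:
    """Simulate + extract fully in memory (no disk IO); used by tests/report."""
    spec = config.cohort_spec()
    subjects, masks, covariates = generate_cohort(spec)
    rows = []
    for sspec, volume in subjects:
        per_muscle = extract_subject_features(
            volume, masks, ng=config.ng,
            distance_correction=config.distance_correction,
            aggregation=config.aggregation,
            use_raw_moments=config.use_raw_moments)
        rows.append(features_to_row(sspec.subject_id, per_muscle))
    return covariates.merge(pd.DataFrame(rows), on="subject_id", how="inner")
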