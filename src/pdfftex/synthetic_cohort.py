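"""Synthetic PDFF phantom cohort with programmed effect structure.

Each subject is a 3D PDFF volume holding six elliptical-cylinder ROIs
(three muscle compartments x two mirror-symmetric sides, each spanning a
fixed number of axial slices). Inside an ROI the signal is

    value = mean_pdff_target + tau * G,  clipped to [0, 100],

where G is Gaussian-smoothed white noise re-standardized to exactly zero
mean and unit variance over the ROI voxels, so the programmed ROI mean and
standard deviation are hit exactly in the unclipped regime.

Cohort-level defaults program the qualitative pattern the downstream
statistics should recover: an erector-spinae mean-PDFF gap favoring
females, male-elevated spatial heterogeneity (tau) in all three muscles,
and per-muscle residual fields that are independent across muscles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import MUSCLES, SIDES
from .volume_io import PDFFVolume, ROIMask

logger = logging.getLogger(__name__)

_MUSCLE_IDX = {m: k for k, m in enumerate(MUSCLES)}
_SIDE_IDX = {s: k for k, s in enumerate(SIDES)}


class MaskSizingError(ValueError):
    """The requested grid cannot hold the six disjoint ROIs."""


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to generate one subject's phantom volume."""

    subject_id: str
    sex: str  # 'male' | 'female'
    age: float  # years
    bmi: float  # kg/m^2
    mean_pdff_target: dict[str, float]  # percent, per muscle
    tau: dict[str, float]  # spatial heterogeneity sd, percent, per muscle
    correlation_length: float = 1.5  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0 or self.bmi <= 0:
            raise ValueError("age and bmi must be positive")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        for m in MUSCLES:
            mp = self.mean_pdff_target[m]
            if not 0.0 <= mp <= 100.0:
                raise ValueError(f"mean_pdff_target[{m}]={mp} outside [0, 100]")
            if self.tau[m] < 0:
                raise ValueError(f"tau[{m}] must be nonnegative")


@dataclass(frozen=True)
class EffectModel:
    """Linear per-muscle effect model (sex, age, bmi) -> mean target and tau.

    mean = intercept[sex] + slope_age*(age - 45) + slope_bmi*(bmi - 24) + e_m
    tau  = tau_intercept[sex] + tau_slope_mean * e_m + e_t

    Coupling tau to the *residual* part of the mean (e_m) produces the
    within-muscle heterogeneity-vs-mean association while leaving the
    between-muscle residual structure independent.
    """

    mean_intercept_male: float
    mean_intercept_female: float
    mean_slope_age: float
    mean_slope_bmi: float
    mean_resid_sd: float
    tau_intercept_male: float
    tau_intercept_female: float
    tau_slope_age: float = 0.0
    tau_slope_bmi: float = 0.0
    tau_slope_mean: float = 0.0
    tau_resid_sd: float = 0.0


def default_effect_models() -> dict[str, EffectModel]:
    """Defaults programming the target qualitative pattern.

    ES mean PDFF ~9 percentage points higher in females; tau higher in
    males in all muscles; tau coupled to the mean residual so heterogeneity
    tracks fat fraction within a muscle. Mean levels are placed high enough
    that clipping at 0 stays negligible.
    """
    return {
        "CE": EffectModel(25.0, 25.0, 0.08, 0.4, 3.0, 8.3, 7.4,
                          tau_slope_mean=0.15, tau_resid_sd=0.4),
        "ES": EffectModel(26.0, 35.0, 0.08, 0.4, 3.0, 11.6, 9.8,
                          tau_slope_mean=0.2, tau_resid_sd=0.4),
        "PS": EffectModel(22.0, 22.0, 0.08, 0.4, 3.0, 9.9, 8.2,
                          tau_slope_mean=0.15, tau_resid_sd=0.4),
    }


@dataclass(frozen=True)
class CohortSpec:
    n_male: int = 25
    n_female: int = 54
    effect_models: dict[str, EffectModel] = field(default_factory=default_effect_models)
    grid_shape: tuple[int, int, int] = (32, 32, 10)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    slices_per_roi: int = 10
    correlation_length: float = 1.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("subject counts must be nonnegative")
        if self.slices_per_roi < 1:
            raise ValueError("slices_per_roi must be >= 1")


# fixed elliptical-cylinder layout, radii in voxels
_ROI_RX = 3.5
_ROI_RY = 3.5
_ROI_Y_FRAC = {"CE": 0.18, "ES": 0.5, "PS": 0.82}
_ROI_X_FRAC_LEFT = 0.25


def make_masks(grid_shape: tuple[int, int, int],
               voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
               slices_per_roi: int = 10,
               rx: float = _ROI_RX, ry: float = _ROI_RY) -> dict[tuple[str, str], ROIMask]:
    """Six pairwise-disjoint elliptical-cylinder ROIs, mirror pairs across x.

    Each mask is nonzero on exactly ``slices_per_roi`` centered axial
    slices; the right mask of each muscle is the x-flip of the left.
    Raises :class:`MaskSizingError` naming the first ROI that does not fit.
    """
    nx, ny, nz = grid_shape
    if nz < slices_per_roi:
        raise MaskSizingError(
            f"grid has {nz} axial slices but {slices_per_roi} are required per ROI"
        )
    z0 = (nz - slices_per_roi) // 2
    z_slice = slice(z0, z0 + slices_per_roi)

    xs = np.arange(nx, dtype=np.float64)
    ys = np.arange(ny, dtype=np.float64)
    cx_left = _ROI_X_FRAC_LEFT * (nx - 1)

    masks: dict[tuple[str, str], ROIMask] = {}
    for muscle in MUSCLES:
        cy = _ROI_Y_FRAC[muscle] * (ny - 1)
        in_ell = (((xs[:, None] - cx_left) / rx) ** 2
                  + ((ys[None, :] - cy) / ry) ** 2) <= 1.0
        if not in_ell.any():
            raise MaskSizingError(f"ROI {muscle}/left is empty at radii ({rx}, {ry})")
        xi, yi = np.nonzero(in_ell)
        # left ROI must sit strictly in the left half so its mirror is disjoint
        if xi.max() >= nx / 2.0 - 0.5 or xi.min() < 0:
            raise MaskSizingError(
                f"ROI {muscle}/left (x extent {xi.min()}..{xi.max()}) does not fit "
                f"in the left half of a {nx}-voxel axis at radius {rx}"
            )
        if yi.min() < 0 or yi.max() >= ny:
            raise MaskSizingError(f"ROI {muscle}/left exceeds the y extent {ny}")
        left = np.zeros(grid_shape, dtype=bool)
        left[:, :, z_slice] = in_ell[:, :, None]
        right = left[::-1, :, :].copy()
        masks[(muscle, "left")] = ROIMask(mask=left, muscle=muscle, side="left")
        masks[(muscle, "right")] = ROIMask(mask=right, muscle=muscle, side="right")

    union = np.zeros(grid_shape, dtype=np.int32)
    for (muscle, side), roi in masks.items():
        union += roi.mask
        if union.max() > 1:
            raise MaskSizingError(f"ROI {muscle}/{side} overlaps a previous ROI")
    return masks


def _correlated_field(shape: tuple[int, int, int], correlation_length: float,
                      rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return gaussian_filter(noise, sigma=correlation_length, mode="nearest")


def generate_subject(spec: SubjectSpec, masks: dict[tuple[str, str], ROIMask],
                     voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
                     ) -> PDFFVolume:
    """Render one phantom volume from a subject spec.

    Per (muscle, side), an independent smoothed-noise field is
    re-standardized over the ROI voxels so the pre-clipping ROI sample mean
    and sd equal the programmed (mean_pdff_target, tau) exactly. With
    tau = 0 every ROI voxel equals the target. Severe clipping (> 50 % of
    an ROI's voxels) is flagged in the volume metadata.
    """
    shape = next(iter(masks.values())).shape
    values = np.zeros(shape, dtype=np.float64)
    clip_flags: dict[str, float] = {}

    for (muscle, side), roi in sorted(masks.items()):
        if roi.shape != shape:
            raise ValueError("all masks must share one grid")
        target = spec.mean_pdff_target[muscle]
        tau = spec.tau[muscle]
        m = roi.mask
        if tau == 0.0:
            roi_vals = np.full(int(m.sum()), target)
        else:
            ss = np.random.SeedSequence(
                entropy=spec.seed,
                spawn_key=(_MUSCLE_IDX[muscle], _SIDE_IDX[side]),
            )
            field_ = _correlated_field(shape, spec.correlation_length,
                                       np.random.default_rng(ss))
            g = field_[m]
            sd = g.std()
            if sd == 0.0:  # single-voxel ROI: no spatial variation possible
                g = np.zeros_like(g)
            else:
                g = (g - g.mean()) / sd
            roi_vals = target + tau * g
        clipped = (roi_vals < 0) | (roi_vals > 100)
        frac = float(clipped.mean()) if clipped.size else 0.0
        if frac > 0.5:
            key = f"{muscle}/{side}"
            clip_flags[key] = frac
            logger.warning("subject %s ROI %s: %.0f%% of voxels clipped; "
                           "programmed moments are distorted",
                           spec.subject_id, key, 100 * frac)
        values[m] = np.clip(roi_vals, 0.0, 100.0)

    meta = {"subject_id": spec.subject_id, "seed": spec.seed}
    if clip_flags:
        meta["severe_clipping"] = clip_flags
    return PDFFVolume(values=values, voxel_size=voxel_size, meta=meta)


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=master_seed,
                                      spawn_key=(index,)).generate_state(1)[0])


def draw_subject_specs(spec: CohortSpec) -> list[SubjectSpec]:
    """Draw covariates and per-muscle targets for the whole cohort.

    Age ~ Uniform(20, 70); BMI ~ Normal(24, 5) truncated at 16. Per-subject
    generator seeds derive deterministically from the master seed and the
    subject index.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.master_seed,
                                                       spawn_key=(10_000,)))
    sexes = ["male"] * spec.n_male + ["female"] * spec.n_female
    out: list[SubjectSpec] = []
    for idx, sex in enumerate(sexes):
        age = float(rng.uniform(20.0, 70.0))
        bmi = float(rng.normal(24.0, 5.0))
        while bmi < 16.0:
            bmi = float(rng.normal(24.0, 5.0))
        means: dict[str, float] = {}
        taus: dict[str, float] = {}
        for muscle in MUSCLES:
            em = spec.effect_models[muscle]
            inter = em.mean_intercept_male if sex == "male" else em.mean_intercept_female
            resid = float(rng.normal(0.0, em.mean_resid_sd))
            mean = (inter + em.mean_slope_age * (age - 45.0)
                    + em.mean_slope_bmi * (bmi - 24.0) + resid)
            t_inter = em.tau_intercept_male if sex == "male" else em.tau_intercept_female
            tau = (t_inter + em.tau_slope_age * (age - 45.0)
                   + em.tau_slope_bmi * (bmi - 24.0)
                   + em.tau_slope_mean * resid
                   + float(rng.normal(0.0, em.tau_resid_sd)))
            means[muscle] = float(np.clip(mean, 0.0, 100.0))
            taus[muscle] = max(0.0, tau)
        out.append(SubjectSpec(
            subject_id=f"S{idx:03d}",
            sex=sex,
            age=age,
            bmi=bmi,
            mean_pdff_target=means,
            tau=taus,
            correlation_length=spec.correlation_length,
            seed=_subject_seed(spec.master_seed, idx),
        ))
    return out


def generate_cohort(spec: CohortSpec) -> tuple[
        list[tuple[SubjectSpec, PDFFVolume]], dict[tuple[str, str], ROIMask], pd.DataFrame]:
    """Generate all subject volumes, the shared mask set, and covariates.

    Returns (subjects, masks, covariates); covariate rows match the subject
    list one-to-one and the whole result is a pure function of the spec.
    """
    masks = make_masks(spec.grid_shape, spec.voxel_size, spec.slices_per_roi)
    specs = draw_subject_specs(spec)
    subjects = [(s, generate_subject(s, masks, spec.voxel_size)) for s in specs]
    covariates = pd.DataFrame({
        "subject_id": [s.subject_id for s in specs],
        "sex": [s.sex for s in specs],
        "age": [s.age for s in specs],
        "bmi": [s.bmi for s in specs],
    })
    return subjects, masks, covariates


def with_master_seed(spec: CohortSpec, master_seed: int) -> CohortSpec:
    return replace(spec, master_seed=master_seed)
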