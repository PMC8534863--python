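"""Volume and mask IO, ROI value extraction, and ROI geometry.

All computation downstream happens in voxel space; world coordinates are
carried through opaquely via the NIfTI affine. Volumes and masks must share
a grid — no resampling is performed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Mask and volume are not defined on the same voxel grid."""


class EmptyROIError(ValueError):
    """An operation was asked to run on an empty ROI."""


@dataclass
class PDFFVolume:
    """A 3D scalar fat-fraction map in percent with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Fat fraction in percent, nominally in [0, 100].
    voxel_size : tuple of float
        Physical voxel spacing in mm per axis; all entries positive.
    affine : ndarray, optional
        4x4 voxel-to-world matrix, passed through opaquely on save.
    meta : dict
        Free-form metadata (e.g. clipping diagnostics from generators).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"PDFF volume must be 3D, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {self.values.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ROIMask:
    """Binary mask on the grid of its paired volume, tagged muscle x side."""

    mask: np.ndarray
    muscle: str
    side: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"ROI mask must be 3D, got {self.mask.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(volume: PDFFVolume, path: str | Path) -> None:
    affine = volume.affine if volume.affine is not None else _default_affine(volume.voxel_size)
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def load_volume(path: str | Path, clamp: bool = True) -> PDFFVolume:
    """Load a 3D NIfTI scalar image as a PDFF volume.

    Values outside [0, 100] are clamped at load time (with a logged count)
    so that gray-level quantization anchored at 0 % and 100 % is total.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar image, got {data.ndim}D")
    meta: dict = {}
    if clamp:
        n_out = int(np.count_nonzero((data < 0) | (data > 100)))
        if n_out:
            logger.info("%s: clamped %d voxels outside [0, 100]", path, n_out)
            data = np.clip(data, 0.0, 100.0)
        meta["n_clamped_at_load"] = n_out
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PDFFVolume(values=data, voxel_size=voxel_size, affine=img.affine, meta=meta)


def save_mask(roi: ROIMask, voxel_size: tuple[float, float, float], path: str | Path,
              affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else _default_affine(voxel_size)
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), aff)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))


def load_mask(path: str | Path, muscle: str, side: str,
              volume: PDFFVolume | None = None) -> ROIMask:
    """Load a binary ROI mask; binarization threshold is > 0.5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask image, got {data.ndim}D")
    mask = data > 0.5
    if volume is not None and mask.shape != volume.shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} does not match volume grid {volume.shape}"
        )
    return ROIMask(mask=mask, muscle=muscle, side=side)


def roi_values(volume: PDFFVolume, roi: ROIMask) -> np.ndarray:
    """Extract in-mask voxel values in fixed scan order (x fastest, then y, then z).

    The fixed order makes every downstream computation bit-reproducible.
    """
    if roi.shape != volume.shape:
        raise GridMismatchError(
            f"mask grid {roi.shape} does not match volume grid {volume.shape}"
        )
    if not roi.mask.any():
        raise EmptyROIError(f"ROI {roi.muscle}/{roi.side} is empty")
    # transpose to (z, y, x) so C-order boolean indexing walks x fastest
    return volume.values.T[roi.mask.T]


def roi_volume_mm3(roi: ROIMask, voxel_size: tuple[float, float, float]) -> float:
    """Geometric ROI volume: voxel count times physical voxel volume."""
    return float(roi.n_voxels) * float(np.prod(voxel_size))


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Load a covariate CSV with columns subject_id, sex, age, bmi."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sex", "age", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in covariate table")
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
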