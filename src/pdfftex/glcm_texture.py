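"""3D gray-level co-occurrence matrix texture features.

PDFF maps are quantized to ``Ng`` equal-width gray levels anchored at 0 %
and 100 %, a single symmetric GLCM is accumulated over the 13 unique
offsets of the 26-neighborhood (so the feature set is invariant to axis
permutations and flips), diagonal pair contributions are down-weighted by
their physical separation, and eight second-order features are read off
the normalized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_NG = 200

# the 13 unique nonzero offsets of {-1,0,1}^3 up to sign
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


class DegenerateROIError(ValueError):
    """ROI has no in-mask voxel pair for any offset."""


@dataclass
class QuantizedROI:
    """Integer labels 1..Ng inside the mask; 0 % -> level 1, 100 % -> level Ng."""

    labels: np.ndarray
    mask: np.ndarray
    ng: int


@dataclass
class GLCMatrix:
    """Normalized symmetric joint-probability matrix over the 13 directions."""

    P: np.ndarray  # (Ng, Ng), sums to 1
    ng: int


@dataclass(frozen=True)
class GLCMFeatures:
    energy: float
    contrast: float
    entropy: float  # bits
    homogeneity: float
    correlation: float  # NaN for constant ROIs
    variance: float
    sum_average: float
    dissimilarity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "contrast": self.contrast,
            "entropy": self.entropy,
            "homogeneity": self.homogeneity,
            "correlation": self.correlation,
            "variance": self.variance,
            "sum_average": self.sum_average,
            "dissimilarity": self.dissimilarity,
        }


def quantize(values: np.ndarray, mask: np.ndarray, ng: int = DEFAULT_NG) -> QuantizedROI:
    """Quantize percent values to gray levels 1..ng, anchored at 0 and 100.

    level = min(ng, floor(v / 100 * ng) + 1); monotone in v.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    in_mask = values[mask]
    if in_mask.size and (in_mask.min() < 0 or in_mask.max() > 100):
        raise ValueError(
            "in-mask PDFF values outside [0, 100]; clamp volumes before quantization"
        )
    labels = np.zeros(values.shape, dtype=np.int32)
    labels[mask] = np.minimum(ng, np.floor(in_mask / 100.0 * ng).astype(np.int64) + 1)
    return QuantizedROI(labels=labels, mask=mask, ng=ng)


def _offset_weight(offset: tuple[int, int, int],
                   voxel_size: tuple[float, float, float]) -> float:
    """Discretization-length correction: min spacing over physical pair distance.

    Unit weight for the shortest-axis neighbor; 1/sqrt(2) and 1/sqrt(3) for
    face and body diagonals at isotropic spacing.
    """
    d_phys = np.asarray(offset, dtype=float) * np.asarray(voxel_size, dtype=float)
    return float(min(voxel_size) / np.linalg.norm(d_phys))


def _pair_histogram(q: QuantizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Unnormalized symmetric co-occurrence counts for one offset."""
    dx, dy, dz = offset
    shape = q.labels.shape
    src = [slice(max(0, -dx), min(shape[0], shape[0] - dx)),
           slice(max(0, -dy), min(shape[1], shape[1] - dy)),
           slice(max(0, -dz), min(shape[2], shape[2] - dz))]
    dst = [slice(max(0, dx), min(shape[0], shape[0] + dx)),
           slice(max(0, dy), min(shape[1], shape[1] + dy)),
           slice(max(0, dz), min(shape[2], shape[2] + dz))]
    a = q.labels[tuple(src)]
    b = q.labels[tuple(dst)]
    both = q.mask[tuple(src)] & q.mask[tuple(dst)]
    li = a[both] - 1
    lj = b[both] - 1
    counts = np.zeros((q.ng, q.ng), dtype=np.float64)
    np.add.at(counts, (li, lj), 1.0)
    np.add.at(counts, (lj, li), 1.0)
    return counts


def build_glcm(q: QuantizedROI,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
               distance_correction: bool = True) -> GLCMatrix:
    """Aggregate the symmetric GLCM over the 13 directions and normalize.

    Each ordered in-mask voxel pair (x, x+d) contributes weight w(d) to both
    P[i, j] and P[j, i]; with ``distance_correction`` off, w(d) = 1.
    """
    P = np.zeros((q.ng, q.ng), dtype=np.float64)
    for offset in OFFSETS_13:
        w = _offset_weight(offset, voxel_size) if distance_correction else 1.0
        P += w * _pair_histogram(q, offset)
    total = P.sum()
    if total == 0:
        raise DegenerateROIError("no in-mask voxel pair for any of the 13 offsets")
    return GLCMatrix(P=P / total, ng=q.ng)


def glcm_features(glcm: GLCMatrix) -> GLCMFeatures:
    """Eight second-order features of a normalized symmetric GLCM.

    Gray levels are indexed 1..Ng. Variance and Sum-average are normalized
    by Ng^2 (toolbox convention). Entropy is in bits. Correlation is NaN
    when the marginal variance is zero (constant ROI).
    """
    P = glcm.P
    ng = glcm.ng
    levels = np.arange(1, ng + 1, dtype=np.float64)
    i = levels[:, None]
    j = levels[None, :]

    p_i = P.sum(axis=1)  # symmetric: row and column marginals coincide
    mu = float(np.sum(levels * p_i))
    sigma2 = float(np.sum((levels - mu) ** 2 * p_i))

    energy = float(np.sum(P**2))
    contrast = float(np.sum((i - j) ** 2 * P))
    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    if sigma2 > 0:
        correlation = (float(np.sum(i * j * P)) - mu**2) / sigma2
    else:
        logger.info("constant ROI: GLCM correlation undefined")
        correlation = float("nan")
    variance = float(np.sum((i - mu) ** 2 * P)) / ng**2
    # sum_{k=2}^{2Ng} k * p_{x+y}(k) collapses to sum_{i,j} (i + j) P(i, j)
    sum_average = float(np.sum((i + j) * P)) / ng**2
    dissimilarity = float(np.sum(np.abs(i - j) * P))

    return GLCMFeatures(
        energy=energy,
        contrast=contrast,
        entropy=entropy,
        homogeneity=homogeneity,
        correlation=correlation,
        variance=variance,
        sum_average=sum_average,
        dissimilarity=dissimilarity,
    )


def glcm_features_per_direction(q: QuantizedROI,
                                voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                                distance_correction: bool = True) -> GLCMFeatures:
    """Alternative aggregation: features per direction, then averaged.

    Provided for sensitivity analysis against the default single-matrix
    aggregation; directions with no valid pair are skipped.
    """
    per_dir: list[dict[str, float]] = []
    for offset in OFFSETS_13:
        w = _offset_weight(offset, voxel_size) if distance_correction else 1.0
        counts = w * _pair_histogram(q, offset)
        total = counts.sum()
        if total == 0:
            continue
        per_dir.append(glcm_features(GLCMatrix(P=counts / total, ng=q.ng)).as_dict())
    if not per_dir:
        raise DegenerateROIError("no in-mask voxel pair for any of the 13 offsets")
    avg = {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    return GLCMFeatures(**avg)


def bilateral_aggregate(left: dict[str, float], right: dict[str, float],
                        volume_left_mm3: float, volume_right_mm3: float) -> dict[str, float]:
    """Volume-weighted average of left/right feature dicts.

    A NaN on one side falls back to the other side's value; the result is
    NaN only when both sides are undefined.
    """
    if volume_left_mm3 < 0 or volume_right_mm3 < 0:
        raise ValueError("ROI volumes must be nonnegative")
    v_total = volume_left_mm3 + volume_right_mm3
    if v_total == 0:
        raise ValueError("bilateral aggregation with both ROI volumes zero")
    out: dict[str, float] = {}
    for key in left.keys() | right.keys():
        fl = left.get(key, float("nan"))
        fr = right.get(key, float("nan"))
        l_ok = np.isfinite(fl) and volume_left_mm3 > 0
        r_ok = np.isfinite(fr) and volume_right_mm3 > 0
        if l_ok and r_ok:
            out[key] = (volume_left_mm3 * fl + volume_right_mm3 * fr) / v_total
        elif l_ok:
            out[key] = fl
        elif r_ok:
            out[key] = fr
        else:
            out[key] = float("nan")
    return out
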