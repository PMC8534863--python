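"""Mean PDFF and global (first-order) intensity-histogram features.

The histogram bin count is the median of Sturges', Scott's and the
Freedman-Diaconis rules; variance, skewness and kurtosis are computed from
the binned histogram (bin centers weighted by relative frequency), with a
raw-moment mode available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .volume_io import EmptyROIError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlobalFeatures:
    mean_pdff: float
    variance_global: float
    skewness_global: float  # NaN for constant ROIs
    kurtosis_global: float  # non-excess convention: normal -> 3

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_pdff": self.mean_pdff,
            "variance_global": self.variance_global,
            "skewness_global": self.skewness_global,
            "kurtosis_global": self.kurtosis_global,
        }


def mean_pdff(values: np.ndarray) -> float:
    """Arithmetic mean of the ROI voxel values (percent)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EmptyROIError("mean_pdff of an empty ROI")
    return float(values.mean())


def _sturges(n: int) -> int:
    return int(math.ceil(math.log2(n))) + 1


def bin_count(values: np.ndarray) -> int:
    """Histogram bin count: median of Sturges', Scott's and Freedman-Diaconis.

    k_Sturges = ceil(log2 n) + 1
    k_Scott   = ceil(range / (3.49 * sd * n^(-1/3)))
    k_FD      = ceil(range / (2 * IQR * n^(-1/3)))

    Degenerate inputs (zero range, zero sd, or zero IQR) fall back to
    Sturges' count so the rule is total.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise ValueError(f"bin_count needs at least 2 values, got {n}")
    k_sturges = _sturges(n)
    vrange = float(values.max() - values.min())
    sd = float(values.std(ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    if vrange == 0.0 or sd == 0.0 or iqr == 0.0:
        return k_sturges
    k_scott = int(math.ceil(vrange / (3.49 * sd * n ** (-1.0 / 3.0))))
    k_fd = int(math.ceil(vrange / (2.0 * iqr * n ** (-1.0 / 3.0))))
    return int(np.median([k_sturges, k_scott, k_fd]))


def _histogram(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [min, max]; returns (centers, rel. freqs)."""
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    freqs = counts / counts.sum()
    return centers, freqs


def global_features(values: np.ndarray, use_raw_moments: bool = False) -> GlobalFeatures:
    """Mean PDFF plus histogram variance, skewness and kurtosis of an ROI.

    Moments are taken over the binned histogram (bin centers x relative
    frequencies) by default. Constant ROIs yield variance 0 and NaN
    skewness/kurtosis.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError(f"global_features needs at least 2 values, got {values.size}")
    mean = float(values.mean())

    if use_raw_moments:
        centers, freqs = values, np.full(values.size, 1.0 / values.size)
    else:
        centers, freqs = _histogram(values, bin_count(values))

    m = float(np.sum(freqs * centers))
    dev = centers - m
    m2 = float(np.sum(freqs * dev**2))
    if m2 == 0.0:
        logger.info("constant ROI: skewness/kurtosis undefined")
        return GlobalFeatures(mean, 0.0, float("nan"), float("nan"))
    m3 = float(np.sum(freqs * dev**3))
    m4 = float(np.sum(freqs * dev**4))
    return GlobalFeatures(
        mean_pdff=mean,
        variance_global=m2,
        skewness_global=m3 / m2**1.5,
        kurtosis_global=m4 / m2**2,
    )
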