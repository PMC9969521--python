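"""Quantitative evaluation of elastograms.

Contrast-to-noise ratio between inclusion and background ROIs,

    CNR(dB) = 20 log10( 2 (mu_b - mu_i)^2 / (sigma_b^2 + sigma_i^2) ),

signed mean error against a reference modulus,

    ME(%) = (mu_e - mu_ref) / mu_ref * 100,

(negative = underestimation, positive = overestimation), and the
Young-to-shear conversion mu = E / (2 (1 + nu)) used to turn mechanical
stress-strain measurements into reference shear moduli.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionStats",
    "region_stats",
    "cnr_db",
    "mean_error_pct",
    "young_to_shear",
]


@dataclass
class RegionStats:
    """Shear-modulus statistics within one region of interest."""

    mean_pa: float
    std_pa: float
    n_voxels: int
    roi_label: str = ""

    def __post_init__(self):
        if self.std_pa < 0:
            raise ValueError("std must be nonnegative")
        if self.n_voxels < 1:
            raise ValueError("a region needs at least one voxel")


def region_stats(volume: np.ndarray, mask: np.ndarray, label: str = "") -> RegionStats:
    """NaN-aware mean and population standard deviation over a mask."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share one shape")
    vals = volume[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"region {label!r} contains no finite voxels")
    return RegionStats(
        mean_pa=float(vals.mean()),
        std_pa=float(vals.std(ddof=0)),
        n_voxels=int(vals.size),
        roi_label=label,
    )


def cnr_db(background: RegionStats, inclusion: RegionStats) -> float:
    """Contrast-to-noise ratio in dB between background and inclusion ROIs.

    Symmetric under swapping the two regions.  Zero contrast returns -inf
    with a warning (a sentinel, so batch evaluation never aborts).
    """
    var_sum = background.std_pa**2 + inclusion.std_pa**2
    if var_sum <= 0:
        raise ValueError("both ROI variances are zero; CNR is undefined")
    contrast = (background.mean_pa - inclusion.mean_pa) ** 2
    if contrast == 0:
        warnings.warn("zero contrast between ROIs; CNR is -inf", RuntimeWarning)
        return -math.inf
    return 20.0 * math.log10(2.0 * contrast / var_sum)


def mean_error_pct(mu_estimated: float, mu_reference: float) -> float:
    """Signed mean error (%) of an estimated modulus against a reference."""
    if mu_reference <= 0:
        raise ValueError("reference modulus must be positive")
    return (mu_estimated - mu_reference) / mu_reference * 100.0


def young_to_shear(E, poisson: float = 0.495):
    """Shear modulus from Young's modulus: mu = E / (2 (1 + nu)).

    The default Poisson ratio 0.495 models nearly incompressible soft
    tissue; nu = 0.5 (exact incompressibility) is excluded.
    """
    if not (-1.0 < poisson < 0.5):
        raise ValueError("poisson ratio must lie in (-1, 0.5)")
    E = np.asarray(E, dtype=float)
    mu = E / (2.0 * (1.0 + poisson))
    return mu if mu.ndim else float(mu)
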