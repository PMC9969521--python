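"""Harmonic extraction, spatial bandpass filtering and phase unwrapping.

The preprocessing chain turns raw phase-offset snapshots into unwrapped
spatial phase volumes per displacement component:

1. temporal Fourier extraction of the complex motion at the vibration
   frequency from >= 3 equally spaced snapshots;
2. a speed-derived annular bandpass in the spatial-frequency plane that
   rejects slow longitudinal bulk motion (below ``k_l = 2*pi*f/c_high``)
   and high-wavenumber noise (above ``k_h = 2*pi*f/c_low``);
3. wrapped phase of each complex component and reliability-ordered 2D
   unwrapping, with slices aligned by per-slice 2*pi offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sp_fft
from skimage.restoration import unwrap_phase as _skimage_unwrap_2d

from .simulate import COMPONENTS, SnapshotSeries, WaveField, _as_spacing_triple

__all__ = [
    "FilterSpec",
    "PhaseVolume",
    "extract_harmonic",
    "bandpass_filter",
    "component_phase",
    "unwrap_phase",
]

#: voxels whose magnitude falls below this fraction of the component's
#: 99th-percentile magnitude are masked NaN before phase extraction
MAGNITUDE_FLOOR_FRACTION = 1e-3


@dataclass
class FilterSpec:
    """Annular spatial bandpass derived from shear-speed bounds.

    The passband in radial wavenumber is [k_l, k_h] with
    k_l = 2*pi*f/c_high and k_h = 2*pi*f/c_low, tapered by raised-cosine
    edges of width ``rolloff`` times each cutoff.  Defaults follow typical
    soft-tissue speeds: c_low = 0.3 m/s, c_high = 3.5 m/s.
    """

    frequency_hz: float
    c_low_m_per_s: float = 0.3
    c_high_m_per_s: float = 3.5
    rolloff: float = 0.1

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if not (0 < self.c_low_m_per_s < self.c_high_m_per_s):
            raise ValueError("need 0 < c_low < c_high")
        if not (0 <= self.rolloff < 0.5):
            raise ValueError("rolloff must be in [0, 0.5)")

    @property
    def k_low_rad_per_m(self) -> float:
        return 2.0 * math.pi * self.frequency_hz / self.c_high_m_per_s

    @property
    def k_high_rad_per_m(self) -> float:
        return 2.0 * math.pi * self.frequency_hz / self.c_low_m_per_s


@dataclass
class PhaseVolume:
    """Spatial phase of one displacement component, wrapped or unwrapped."""

    values: np.ndarray
    component_label: str
    wrapped: bool
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D volume")
        if self.component_label not in COMPONENTS:
            raise ValueError(f"component_label must be one of {COMPONENTS}")
        self.voxel_spacing_mm = _as_spacing_triple(self.voxel_spacing_mm)
        if self.wrapped:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
                raise ValueError("wrapped phase must lie in (-pi, pi]")


def extract_harmonic(series: SnapshotSeries) -> WaveField:
    """Complex motion at the vibration frequency from temporal snapshots.

    The fundamental bin of the temporal DFT is scaled by 2/n so that a
    series ``Re{A exp(i*phi0) exp(-i*w*t)}`` returns exactly
    ``A exp(i*phi0)``; DC is rejected.
    """
    n = series.n_offsets
    if n < 3:
        raise ValueError("need at least 3 phase offsets")
    expected = 2.0 * np.pi * np.arange(n) / n
    if not np.allclose(series.offset_phase_rad, expected, atol=1e-9):
        raise ValueError("phase offsets must be equally spaced as 2*pi*m/n")
    weights = np.exp(1j * expected)
    data = (2.0 / n) * np.tensordot(weights, series.data, axes=(0, 0))
    return WaveField(
        data=data,
        voxel_spacing_mm=series.voxel_spacing_mm,
        frequency_hz=series.frequency_hz,
    )


def _annular_weight(kr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    k_l, k_h = spec.k_low_rad_per_m, spec.k_high_rad_per_m
    w_l = spec.rolloff * k_l
    w_h = spec.rolloff * k_h
    if k_l + w_l >= k_h - w_h:
        raise ValueError("passband vanishes for the requested taper widths")
    w = np.zeros_like(kr)
    rising = (kr >= k_l) & (kr < k_l + w_l)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * (kr[rising] - k_l) / w_l)) if w_l > 0 else 1.0
    flat = (kr >= k_l + w_l) & (kr <= k_h - w_h)
    w[flat] = 1.0
    falling = (kr > k_h - w_h) & (kr <= k_h)
    if w_h > 0:
        w[falling] = 0.5 * (1.0 + np.cos(np.pi * (kr[falling] - (k_h - w_h)) / w_h))
    else:
        w[falling] = 1.0
    return w


def _filter_plane(data: np.ndarray, axes: tuple[int, int], spacing_m, spec: FilterSpec) -> np.ndarray:
    """Apply the annular filter in the plane spanned by `axes` of a 3D array."""
    n0, n1 = data.shape[axes[0]], data.shape[axes[1]]
    k0 = 2.0 * np.pi * sp_fft.fftfreq(n0, d=spacing_m[axes[0]])
    k1 = 2.0 * np.pi * sp_fft.fftfreq(n1, d=spacing_m[axes[1]])
    kr = np.sqrt(k0[:, None] ** 2 + k1[None, :] ** 2)
    weight = _annular_weight(kr, spec)
    if not np.any(weight > 0):
        raise ValueError(
            "grid too small: no spatial-frequency sample falls in the passband"
        )
    shape = [1, 1, 1]
    shape[axes[0]], shape[axes[1]] = n0, n1
    spec_w = weight.reshape(shape)
    F = sp_fft.fftn(data, axes=axes)
    return sp_fft.ifftn(F * spec_w, axes=axes)


def bandpass_filter(field: WaveField, spec: FilterSpec, mode: str = "slicewise") -> WaveField:
    """Suppress longitudinal bulk motion and high-wavenumber noise.

    ``mode="slicewise"`` (default) applies the 2D annular filter
    independently in each of the three orthogonal slice orientations and
    averages the three results; ``mode="radial3d"`` applies a single 3D
    radial annulus for comparison.
    """
    spacing_m = [s * 1e-3 for s in field.voxel_spacing_mm]
    out = np.empty_like(field.data, dtype=complex)
    plane_axes = [(1, 2), (0, 2), (0, 1)]  # slice normals along x, y, z
    for c in range(3):
        vol = field.data[c]
        if mode == "slicewise":
            acc = np.zeros_like(vol, dtype=complex)
            for axes in plane_axes:
                acc += _filter_plane(vol, axes, spacing_m, spec)
            out[c] = acc / 3.0
        elif mode == "radial3d":
            ks = [
                2.0 * np.pi * sp_fft.fftfreq(n, d=d)
                for n, d in zip(vol.shape, spacing_m)
            ]
            kr = np.sqrt(
                ks[0][:, None, None] ** 2 + ks[1][None, :, None] ** 2 + ks[2][None, None, :] ** 2
            )
            weight = _annular_weight(kr, spec)
            if not np.any(weight > 0):
                raise ValueError(
                    "grid too small: no spatial-frequency sample falls in the passband"
                )
            out[c] = sp_fft.ifftn(sp_fft.fftn(vol) * weight)
        else:
            raise ValueError("mode must be 'slicewise' or 'radial3d'")
    return WaveField(
        data=out,
        voxel_spacing_mm=field.voxel_spacing_mm,
        frequency_hz=field.frequency_hz,
        mask=field.mask,
        ground_truth_k_map=field.ground_truth_k_map,
    )


def component_phase(
    field: WaveField,
    component: str,
    magnitude_floor_fraction: float = MAGNITUDE_FLOOR_FRACTION,
) -> PhaseVolume:
    """Wrapped spatial phase of one complex displacement component.

    The phase is the complex argument mapped to (-pi, pi].  Voxels whose
    magnitude falls below ``magnitude_floor_fraction`` of the component's
    99th-percentile magnitude are masked NaN (their phase is noise).
    """
    comp = field.component(component)
    phase = np.angle(comp)
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    phase = np.where(phase <= -np.pi, np.pi, phase)
    mag = np.abs(comp)
    floor = magnitude_floor_fraction * np.nanpercentile(mag, 99)
    phase = np.where(mag < floor, np.nan, phase)
    if field.mask is not None:
        phase = np.where(field.mask, phase, np.nan)
    return PhaseVolume(
        values=phase,
        component_label=component,
        wrapped=True,
        voxel_spacing_mm=field.voxel_spacing_mm,
    )


def unwrap_phase(phase: PhaseVolume, slice_axis: int = 2) -> PhaseVolume:
    """Unwrap wrapped phase slice-by-slice, then align slices.

    Each 2D slice perpendicular to ``slice_axis`` is unwrapped with a
    reliability-ordered algorithm; slices are then aligned sequentially by
    adding the integer multiple of 2*pi that minimizes the median
    slice-to-slice jump.  Output minus input is an integer multiple of
    2*pi at every voxel, up to that per-slice constant.
    """
    if not phase.wrapped:
        raise ValueError("phase is already unwrapped")
    vol = np.moveaxis(phase.values.copy(), slice_axis, -1)
    n_slices = vol.shape[-1]
    out = np.full_like(vol, np.nan)
    for j in range(n_slices):
        sl = vol[..., j]
        invalid = ~np.isfinite(sl)
        if invalid.all():
            raise ValueError(f"slice {j} along axis {slice_axis} is entirely NaN")
        if invalid.any():
            masked = np.ma.masked_array(np.nan_to_num(sl), mask=invalid)
            unwrapped = np.asarray(_skimage_unwrap_2d(masked))
            unwrapped[invalid] = np.nan
        else:
            unwrapped = _skimage_unwrap_2d(sl)
        out[..., j] = unwrapped
    # sequential inter-slice alignment by whole 2*pi offsets
    two_pi = 2.0 * np.pi
    for j in range(1, n_slices):
        both = np.isfinite(out[..., j]) & np.isfinite(out[..., j - 1])
        if not both.any():
            continue
        jump = np.median(out[..., j][both] - out[..., j - 1][both])
        out[..., j] -= two_pi * np.round(jump / two_pi)
    return PhaseVolume(
        values=np.moveaxis(out, -1, slice_axis),
        component_label=phase.component_label,
        wrapped=False,
        voxel_spacing_mm=phase.voxel_spacing_mm,
    )
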