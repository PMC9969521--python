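"""Local wavenumber estimation by phase-gradient plane fits.

Within overlapping 3D kernels the unwrapped phase of a reverberant field is
locally planar, ``phi(x, y, z) ~ k_x x + k_y y + k_z z + c0``, and the local
wavenumber follows ``k^2 = A (k_x^2 + k_y^2 + k_z^2)`` with the scaling
constant A taken as 1.  Shear-wave speed and modulus follow as
``c = 2*pi*f / k`` and ``mu = rho c^2``.  The composite elastogram is the
voxelwise mean of the per-component modulus maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sp_linalg
from scipy import ndimage

from .preprocess import (
    MAGNITUDE_FLOOR_FRACTION,
    FilterSpec,
    PhaseVolume,
    bandpass_filter,
    component_phase,
    unwrap_phase,
)
from .simulate import COMPONENTS, WaveField

__all__ = [
    "KernelSpec",
    "ElastogramSet",
    "fit_phase_plane",
    "estimate_phase_gradient_maps",
    "estimate_wavenumber_map",
    "wavenumber_to_speed",
    "speed_to_modulus",
    "composite_elastogram",
    "reconstruct",
]


@dataclass
class KernelSpec:
    """Geometry of the overlapping plane-fit kernels.

    ``size_mm`` is converted to voxels per axis as
    ``max(3, round(size_mm / spacing))``; at the 1.6 mm phantom resolution
    the 6.4 mm default gives 4x4x4-voxel kernels.
    """

    size_mm: float = 6.4
    stride_voxels: int = 1
    min_valid_fraction: float = 0.8

    def __post_init__(self):
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if int(self.stride_voxels) < 1:
            raise ValueError("stride_voxels must be >= 1")
        self.stride_voxels = int(self.stride_voxels)
        if not (0 < self.min_valid_fraction <= 1):
            raise ValueError("min_valid_fraction must be in (0, 1]")

    def size_voxels(self, voxel_spacing_mm) -> tuple[int, int, int]:
        return tuple(
            max(3, int(round(self.size_mm / s))) for s in voxel_spacing_mm
        )


@dataclass
class ElastogramSet:
    """Per-component and composite wavenumber / speed / modulus maps.

    The stored maps satisfy ``c = 2*pi*f/k`` and ``mu = rho*c^2`` exactly;
    ``composite_mu`` is the voxelwise mean of the defined per-component
    modulus maps.
    """

    per_component: dict
    composite_mu: np.ndarray
    density_kg_per_m3: float
    frequency_hz: float
    scaling_constant_A: float = 1.0
    provenance: dict = dc_field(default_factory=dict)

    def k(self, component: str) -> np.ndarray:
        return self.per_component[component]["k"]

    def c(self, component: str) -> np.ndarray:
        return self.per_component[component]["c"]

    def mu(self, component: str) -> np.ndarray:
        return self.per_component[component]["mu"]


def fit_phase_plane(phase_values: np.ndarray, coords: np.ndarray, min_valid_fraction: float = 0.8):
    """Least-squares plane fit ``phi ~ k_x x + k_y y + k_z z + c0``.

    Parameters
    ----------
    phase_values : array
        Unwrapped phase samples of one kernel (any shape; flattened).
    coords : array, shape (n, 3)
        Voxel positions in meters, centered on the kernel centroid.
    min_valid_fraction : float
        Minimum fraction of finite samples; below it the result is the
        flagged NaN quadruple.

    Returns
    -------
    (k_x, k_y, k_z, c0) in rad/m and rad, via an SVD-backed solver.
    """
    phi = np.asarray(phase_values, dtype=float).ravel()
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if phi.size != xyz.shape[0]:
        raise ValueError("phase_values and coords disagree in length")
    valid = np.isfinite(phi)
    if valid.sum() < max(4, min_valid_fraction * phi.size):
        return (np.nan, np.nan, np.nan, np.nan)
    xyz_v = xyz[valid] - xyz[valid].mean(axis=0)
    design = np.column_stack([xyz_v, np.ones(valid.sum())])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate kernel geometry: coordinate matrix is rank-deficient")
    sol, *_ = sp_linalg.lstsq(design, phi[valid], lapack_driver="gelsd")
    return (float(sol[0]), float(sol[1]), float(sol[2]), float(sol[3]))


def _kernel_offsets_m(sizes, spacing_mm):
    return [
        (np.arange(s) - (s - 1) / 2.0) * (d * 1e-3) for s, d in zip(sizes, spacing_mm)
    ]


def estimate_phase_gradient_maps(phase: PhaseVolume, kernel: KernelSpec):
    """Dense maps of the plane-fit phase-gradient components (rad/m).

    A fast separable path handles kernels whose every voxel is finite (the
    centered least-squares normal matrix is diagonal there, so each slope is
    a correlation with fixed weights).  Kernels touching NaN voxels fall
    back to explicit masked plane fits when at least ``min_valid_fraction``
    of their voxels are finite; kernels truncated by the volume boundary
    stay NaN.
    """
    if phase.wrapped:
        raise ValueError("phase must be unwrapped before gradient estimation")
    vol = phase.values
    sizes = kernel.size_voxels(phase.voxel_spacing_mm)
    if any(s > n for s, n in zip(sizes, vol.shape)):
        raise ValueError("kernel is larger than the volume")
    offsets = _kernel_offsets_m(sizes, phase.voxel_spacing_mm)
    n_kernel = int(np.prod(sizes))

    grads = []
    for axis in range(3):
        w = np.zeros(sizes)
        shape = [1, 1, 1]
        shape[axis] = sizes[axis]
        o = offsets[axis].reshape(shape)
        w += o  # broadcast along the other two axes
        sxx = float(np.sum(w**2))
        grads.append(
            ndimage.correlate(vol, w / sxx, mode="constant", cval=np.nan)
        )

    # fallback for partially valid kernels that the NaN-propagating
    # correlation wiped out
    finite = np.isfinite(vol)
    if not finite.all():
        counts = ndimage.correlate(
            finite.astype(float), np.ones(sizes), mode="constant", cval=0.0
        )
        need = (
            ~np.isfinite(grads[0])
            & (counts >= kernel.min_valid_fraction * n_kernel)
            & (counts < n_kernel)
        )
        # restrict to kernels fully inside the volume
        inside = np.zeros_like(need)
        lo = [s // 2 for s in sizes]
        hi = [n - s + s // 2 for n, s in zip(vol.shape, sizes)]
        inside[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        need &= inside
        if need.any():
            coords = np.stack(
                np.meshgrid(*offsets, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            for i, j, kk in zip(*np.nonzero(need)):
                window = vol[
                    i - lo[0] : i - lo[0] + sizes[0],
                    j - lo[1] : j - lo[1] + sizes[1],
                    kk - lo[2] : kk - lo[2] + sizes[2],
                ]
                gx, gy, gz, _ = fit_phase_plane(
                    window, coords, kernel.min_valid_fraction
                )
                grads[0][i, j, kk] = gx
                grads[1][i, j, kk] = gy
                grads[2][i, j, kk] = gz

    if kernel.stride_voxels > 1:
        keep = np.zeros(vol.shape, dtype=bool)
        s = kernel.stride_voxels
        keep[::s, ::s, ::s] = True
        for g in grads:
            g[~keep] = np.nan
    return tuple(grads)


def estimate_wavenumber_map(
    phase: PhaseVolume, kernel: Optional[KernelSpec] = None, A: float = 1.0
) -> np.ndarray:
    """Local wavenumber map ``k = sqrt(A (k_x^2 + k_y^2 + k_z^2))`` (rad/m)."""
    kernel = kernel or KernelSpec()
    gx, gy, gz = estimate_phase_gradient_maps(phase, kernel)
    return np.sqrt(A * (gx**2 + gy**2 + gz**2))


def wavenumber_to_speed(k, f: float):
    """Shear-wave speed ``c = 2*pi*f/k`` (m/s); nonpositive k maps to NaN."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    k = np.asarray(k, dtype=float)
    nonpos = np.isfinite(k) & (k <= 0)
    n_bad = int(nonpos.sum())
    if n_bad:
        warnings.warn(f"{n_bad} nonpositive wavenumber(s) mapped to NaN", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * math.pi * f / k
    c = np.where(nonpos, np.nan, c)
    return c if c.ndim else float(c)


def speed_to_modulus(c, density_kg_per_m3: float = 1000.0):
    """Shear modulus ``mu = rho c^2`` (Pa); default density 1000 kg/m^3."""
    if density_kg_per_m3 < 0:
        raise ValueError("density must be nonnegative")
    c = np.asarray(c, dtype=float)
    mu = density_kg_per_m3 * c**2
    return mu if mu.ndim else float(mu)


def composite_elastogram(mu_x, mu_y, mu_z) -> np.ndarray:
    """Voxelwise mean of the finite per-component modulus maps."""
    maps = [np.asarray(m, dtype=float) for m in (mu_x, mu_y, mu_z)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValueError("component maps must share one grid")
    stacked = np.stack(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        return np.nanmean(stacked, axis=0)


def reconstruct(
    field: WaveField,
    kernel: Optional[KernelSpec] = None,
    filter_spec: Optional[FilterSpec] = None,
    A: float = 1.0,
    density_kg_per_m3: float = 1000.0,
    bandpass: bool = True,
    filter_mode: str = "slicewise",
    components=COMPONENTS,
    magnitude_floor_fraction: float = MAGNITUDE_FLOOR_FRACTION,
) -> ElastogramSet:
    """End-to-end elastogram reconstruction for a complex wave field.

    Per component: bandpass -> wrapped phase -> 2D unwrap -> kernel
    plane-fit wavenumber -> speed -> modulus; the composite elastogram
    averages the per-component modulus maps voxelwise.
    """
    kernel = kernel or KernelSpec()
    if filter_spec is None:
        filter_spec = FilterSpec(frequency_hz=field.frequency_hz)
    f = field.frequency_hz

    work = field
    if bandpass:
        try:
            work = bandpass_filter(field, filter_spec, mode=filter_mode)
        except Exception as exc:
            raise RuntimeError(f"[bandpass] {exc}") from exc

    per_component = {}
    for label in components:
        try:
            wrapped = component_phase(work, label, magnitude_floor_fraction)
            unwrapped = unwrap_phase(wrapped)
        except Exception as exc:
            raise RuntimeError(f"[phase/{label}] {exc}") from exc
        try:
            k_map = estimate_wavenumber_map(unwrapped, kernel, A=A)
        except Exception as exc:
            raise RuntimeError(f"[wavenumber/{label}] {exc}") from exc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c_map = wavenumber_to_speed(k_map, f)
        mu_map = speed_to_modulus(c_map, density_kg_per_m3)
        per_component[label] = {"k": k_map, "c": c_map, "mu": mu_map}

    if set(components) == set(COMPONENTS):
        composite = composite_elastogram(
            per_component["X"]["mu"], per_component["Y"]["mu"], per_component["Z"]["mu"]
        )
    else:
        stacked = np.stack([per_component[c]["mu"] for c in components])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            composite = np.nanmean(stacked, axis=0)

    provenance = {
        "frequency_hz": f,
        "voxel_spacing_mm": list(field.voxel_spacing_mm),
        "kernel_size_mm": kernel.size_mm,
        "kernel_size_voxels": list(kernel.size_voxels(field.voxel_spacing_mm)),
        "stride_voxels": kernel.stride_voxels,
        "min_valid_fraction": kernel.min_valid_fraction,
        "bandpass": bandpass,
        "filter_mode": filter_mode if bandpass else None,
        "c_low_m_per_s": filter_spec.c_low_m_per_s if bandpass else None,
        "c_high_m_per_s": filter_spec.c_high_m_per_s if bandpass else None,
        "rolloff": filter_spec.rolloff if bandpass else None,
        "A": A,
        "density_kg_per_m3": density_kg_per_m3,
        "components": list(components),
        "magnitude_floor_fraction": magnitude_floor_fraction,
    }
    return ElastogramSet(
        per_component=per_component,
        composite_mu=composite,
        density_kg_per_m3=density_kg_per_m3,
        frequency_hz=f,
        scaling_constant_A=A,
        provenance=provenance,
    )
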