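"""Synthetic reverberant shear-wave fields with known ground truth.

A reverberant field is the superposition of many plane shear waves with
random propagation directions, transverse polarizations and random phases:

    V(r) = sum_q  n_q * v_q * exp(i (k d_q . r + theta_q))

where d_q is a unit propagation direction drawn uniformly on the sphere,
n_q a unit polarization drawn uniformly in the plane perpendicular to d_q,
v_q the amplitude and theta_q a uniform phase.  All waves share a single
wavenumber k = 2*pi*f / c set by the vibration frequency f and the true
shear-wave speed c of the medium.  Such fields are statistically isotropic
and serve as ground truth for every downstream estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "WaveField",
    "PhantomSpec",
    "SnapshotSeries",
    "simulate_reverberant_field",
    "make_piecewise_phantom_field",
    "sample_phase_offsets",
    "add_noise",
]

COMPONENTS = ("X", "Y", "Z")


def _as_spacing_triple(spacing) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or np.any(arr <= 0):
        raise ValueError("voxel spacing must be a positive scalar or triple")
    return tuple(float(v) for v in arr)


@dataclass
class SimulationConfig:
    """Parameters of a single-region reverberant field simulation.

    Parameters
    ----------
    grid_shape : tuple of int
        Voxel counts (nx, ny, nz); each axis must have at least 8 voxels so
        kernel-based inversion has room to operate.
    voxel_spacing_mm : float or triple
        Isotropic voxel edge in mm, or a per-axis triple.
    frequency_hz : float
        Vibration frequency f; the angular frequency is 2*pi*f.
    true_speed_m_per_s : float
        Shear-wave speed of the medium; k = 2*pi*f / c.
    n_sources : int
        Number of incident plane waves (10 gives a directed field, 100 a
        fully reverberant one).
    amplitude_model : {"unit", "rayleigh"}
        Per-wave amplitude law; "rayleigh" is scaled so E[v^2] = 1.
    rng_seed : int
        Seed; identical configs give bit-identical fields.
    noise_snr_db : float, optional
        If set, complex Gaussian noise at this SNR is added after synthesis.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: float | tuple[float, float, float] = 1.6
    frequency_hz: float = 50.0
    true_speed_m_per_s: float = 2.0
    n_sources: int = 100
    amplitude_model: str = "unit"
    rng_seed: int = 0
    noise_snr_db: Optional[float] = None

    def __post_init__(self):
        shape = tuple(int(n) for n in self.grid_shape)
        if len(shape) != 3 or any(n < 8 for n in shape):
            raise ValueError("grid_shape must be three integers, each >= 8")
        self.grid_shape = shape
        self.voxel_spacing_mm = _as_spacing_triple(self.voxel_spacing_mm)
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.true_speed_m_per_s <= 0:
            raise ValueError("true_speed_m_per_s must be positive")
        if int(self.n_sources) < 1:
            raise ValueError("n_sources must be >= 1")
        self.n_sources = int(self.n_sources)
        if self.amplitude_model not in ("unit", "rayleigh"):
            raise ValueError("amplitude_model must be 'unit' or 'rayleigh'")
        wavelength_m = self.true_speed_m_per_s / self.frequency_hz
        if wavelength_m < 2 * min(self.voxel_spacing_mm) * 1e-3:
            raise ValueError(
                "shear wavelength spans fewer than 2 voxels; refine the grid "
                "or lower the frequency"
            )

    @property
    def wavenumber_rad_per_m(self) -> float:
        return 2.0 * math.pi * self.frequency_hz / self.true_speed_m_per_s


@dataclass
class WaveField:
    """Complex 3-component harmonic displacement field on a regular grid.

    ``data`` has shape (3, nx, ny, nz) with components ordered X, Y, Z.
    Simulated fields carry ``ground_truth_k_map`` (rad/m) for validation.
    """

    data: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    frequency_hz: float
    mask: Optional[np.ndarray] = None
    ground_truth_k_map: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("data must have shape (3, nx, ny, nz)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(complex)
        self.voxel_spacing_mm = _as_spacing_triple(self.voxel_spacing_mm)
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask shape must match the grid")
        if self.ground_truth_k_map is not None:
            gt = np.asarray(self.ground_truth_k_map, dtype=float)
            if gt.shape != self.grid_shape:
                raise ValueError("ground_truth_k_map shape must match the grid")
            if np.any(gt[np.isfinite(gt)] <= 0):
                raise ValueError("ground_truth_k_map must be positive where defined")
            self.ground_truth_k_map = gt

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def component(self, label: str) -> np.ndarray:
        if label not in COMPONENTS:
            raise ValueError(f"unknown component {label!r}; expected one of {COMPONENTS}")
        return self.data[COMPONENTS.index(label)]


@dataclass
class PhantomSpec:
    """Geometry of a piecewise-homogeneous inclusion phantom.

    Inclusions are spheres given as (center_mm, diameter_mm, modulus_pa);
    centers are measured from the corner voxel (0, 0, 0) of the grid.
    """

    background_modulus_pa: float = 3340.0
    inclusions: Sequence[tuple[tuple[float, float, float], float, float]] = field(
        default_factory=list
    )
    density_kg_per_m3: float = 1000.0

    def __post_init__(self):
        if self.background_modulus_pa <= 0:
            raise ValueError("background modulus must be positive")
        if self.density_kg_per_m3 <= 0:
            raise ValueError("density must be positive")
        for center, diameter, modulus in self.inclusions:
            if diameter <= 0:
                raise ValueError("inclusion diameters must be positive")
            if modulus <= 0:
                raise ValueError("inclusion moduli must be positive")
            if len(center) != 3:
                raise ValueError("inclusion centers must be 3-vectors (mm)")


@dataclass
class SnapshotSeries:
    """Real-valued snapshots of harmonic motion at equally spaced phase offsets."""

    data: np.ndarray  # (n_offsets, 3, nx, ny, nz)
    offset_phase_rad: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    frequency_hz: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n_offsets, 3, nx, ny, nz)")
        self.offset_phase_rad = np.asarray(self.offset_phase_rad, dtype=float)
        if self.offset_phase_rad.shape != (self.data.shape[0],):
            raise ValueError("offset_phase_rad must list one phase per snapshot")
        self.voxel_spacing_mm = _as_spacing_triple(self.voxel_spacing_mm)

    @property
    def n_offsets(self) -> int:
        return self.data.shape[0]


def _draw_sources(rng: np.random.Generator, n_sources: int, amplitude_model: str):
    """Draw (directions, polarizations, phases, amplitudes) for n_sources waves.

    Directions are uniform on the unit sphere (normalized Gaussian draws);
    polarizations are uniform on the circle perpendicular to each direction,
    so every wave is a transverse shear wave.
    """
    directions = rng.standard_normal((n_sources, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    # Orthonormal transverse basis per direction: pick the axis least aligned
    # with d to avoid degeneracy, then Gram-Schmidt.
    helper = np.zeros_like(directions)
    helper[np.arange(n_sources), np.argmin(np.abs(directions), axis=1)] = 1.0
    e1 = np.cross(directions, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(directions, e1)

    psi = rng.uniform(0.0, 2.0 * np.pi, size=n_sources)
    polarizations = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2

    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sources)
    if amplitude_model == "unit":
        amplitudes = np.ones(n_sources)
    else:  # rayleigh with E[v^2] = 1
        amplitudes = rng.rayleigh(scale=1.0 / math.sqrt(2.0), size=n_sources)
    return directions, polarizations, phases, amplitudes


def _grid_coords_m(shape, spacing_mm):
    axes = [np.arange(n, dtype=float) * (s * 1e-3) for n, s in zip(shape, spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def simulate_reverberant_field(config: SimulationConfig) -> WaveField:
    """Synthesize the complex harmonic displacement field at t = 0.

    Returns a :class:`WaveField` whose ``ground_truth_k_map`` is filled with
    the single true wavenumber k = 2*pi*f/c everywhere.  Deterministic for a
    given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    k = config.wavenumber_rad_per_m
    directions, polarizations, phases, amplitudes = _draw_sources(
        rng, config.n_sources, config.amplitude_model
    )

    X, Y, Z = _grid_coords_m(config.grid_shape, config.voxel_spacing_mm)
    data = np.zeros((3,) + config.grid_shape, dtype=complex)
    for q in range(config.n_sources):
        dq = directions[q]
        carrier = np.exp(1j * (k * (dq[0] * X + dq[1] * Y + dq[2] * Z) + phases[q]))
        carrier *= amplitudes[q]
        for c in range(3):
            data[c] += polarizations[q, c] * carrier

    out = WaveField(
        data=data,
        voxel_spacing_mm=config.voxel_spacing_mm,
        frequency_hz=config.frequency_hz,
        ground_truth_k_map=np.full(config.grid_shape, k),
    )
    if config.noise_snr_db is not None:
        out = add_noise(out, config.noise_snr_db, rng_seed=config.rng_seed + 1)
        out.ground_truth_k_map = np.full(config.grid_shape, k)
    return out


def make_piecewise_phantom_field(
    spec: PhantomSpec, config: SimulationConfig, blend_voxels: float = 1.5
) -> WaveField:
    """Piecewise-homogeneous inclusion-phantom fixture.

    Each region (background, inclusions) is filled with an independent
    reverberant field whose wavenumber follows k = 2*pi*f*sqrt(rho/mu) for
    that region's modulus.  This is a geometric fixture for testing
    estimator locality and contrast: fields are cross-faded at region
    boundaries over ``blend_voxels`` voxels (a hard stitch would place
    phase discontinuities on every slice, which 2D unwrapping turns into
    volume-wide artifacts) and there is no refraction or mode conversion,
    so it is not a physical wave solution near interfaces.
    ``ground_truth_k_map`` stays sharply piecewise.
    """
    shape = config.grid_shape
    spacing = config.voxel_spacing_mm
    extent_mm = [n * s for n, s in zip(shape, spacing)]

    # validate geometry: inside grid, pairwise non-overlapping
    for center, diameter, _ in spec.inclusions:
        r = diameter / 2.0
        for c, ext in zip(center, extent_mm):
            if c - r < 0 or c + r > ext:
                raise ValueError("inclusion extends outside the grid")
    incs = list(spec.inclusions)
    for i in range(len(incs)):
        for j in range(i + 1, len(incs)):
            ci, di, _ = incs[i]
            cj, dj, _ = incs[j]
            if np.linalg.norm(np.subtract(ci, cj)) < (di + dj) / 2.0:
                raise ValueError("inclusions overlap")

    rho = spec.density_kg_per_m3
    X, Y, Z = _grid_coords_m(shape, spacing)
    Xmm, Ymm, Zmm = X * 1e3, Y * 1e3, Z * 1e3

    # signed distance (mm) to each inclusion surface: negative inside
    mean_spacing = float(np.mean(spacing))
    inc_signed = []
    inc_moduli = []
    for center, diameter, modulus in incs:
        dist = np.sqrt(
            (Xmm - center[0]) ** 2 + (Ymm - center[1]) ** 2 + (Zmm - center[2]) ** 2
        )
        inc_signed.append(dist - diameter / 2.0)
        inc_moduli.append(modulus)

    # one shared source set: regions differ only in wavenumber, and each
    # inclusion's waves are phase-referenced at its center, so region
    # transitions stay nearly coherent (a fully incoherent stitch breaks
    # slice-to-slice phase consistency throughout the inclusion)
    rng = np.random.default_rng(config.rng_seed)
    directions, polarizations, phases, amplitudes = _draw_sources(
        rng, config.n_sources, config.amplitude_model
    )
    k_bg = 2.0 * math.pi * config.frequency_hz / math.sqrt(
        spec.background_modulus_pa / rho
    )

    def region_field(k_region, ref_mm):
        out = np.zeros((3,) + shape, dtype=complex)
        ref_m = np.asarray(ref_mm) * 1e-3
        for q in range(len(directions)):
            dq = directions[q]
            # phase matched to the background wave at the reference point
            proj = dq[0] * (X - ref_m[0]) + dq[1] * (Y - ref_m[1]) + dq[2] * (Z - ref_m[2])
            ref_phase = k_bg * float(np.dot(dq, ref_m))
            carrier = amplitudes[q] * np.exp(
                1j * (k_region * proj + ref_phase + phases[q])
            )
            for c in range(3):
                out[c] += polarizations[q, c] * carrier
        return out

    data = region_field(k_bg, (0.0, 0.0, 0.0))
    k_map = np.full(shape, k_bg)
    blend_mm = max(blend_voxels * mean_spacing, 1e-9)
    for signed, (center_mm, _, mu_r) in zip(inc_signed, incs):
        k_r = 2.0 * math.pi * config.frequency_hz / math.sqrt(mu_r / rho)
        field_r = region_field(k_r, center_mm)
        # smooth weight: 1 inside, 0 outside, cosine ramp across the surface
        t = np.clip((signed + blend_mm / 2.0) / blend_mm, 0.0, 1.0)
        w = 0.5 * (1.0 + np.cos(np.pi * t))
        data = data * (1.0 - w) + field_r * w
        k_map[signed <= 0] = k_r

    out = WaveField(
        data=data,
        voxel_spacing_mm=spacing,
        frequency_hz=config.frequency_hz,
        ground_truth_k_map=k_map,
    )
    if config.noise_snr_db is not None:
        out = add_noise(out, config.noise_snr_db, rng_seed=config.rng_seed + 97)
        out.ground_truth_k_map = k_map
    return out


def sample_phase_offsets(field: WaveField, n_offsets: int) -> SnapshotSeries:
    """Real motion snapshots Re{ V exp(-i 2*pi*m/n) } for m = 0..n-1.

    Emulates MR acquisition at equally spaced temporal phase offsets within
    one vibration period.  At least 3 offsets are required to separate the
    fundamental from DC without aliasing.
    """
    n_offsets = int(n_offsets)
    if n_offsets < 3:
        raise ValueError("n_offsets must be >= 3 to avoid temporal aliasing")
    phases = 2.0 * np.pi * np.arange(n_offsets) / n_offsets
    snaps = np.real(field.data[None] * np.exp(-1j * phases)[:, None, None, None, None])
    return SnapshotSeries(
        data=snaps,
        offset_phase_rad=phases,
        voxel_spacing_mm=field.voxel_spacing_mm,
        frequency_hz=field.frequency_hz,
    )


def add_noise(field: WaveField, snr_db: float, rng_seed: int) -> WaveField:
    """Add i.i.d. complex Gaussian noise at the requested field-wide SNR.

    The noise variance is set per call from the empirical signal power so
    that 10*log10(P_signal / P_noise) equals ``snr_db`` in expectation.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(rng_seed)
    p_signal = float(np.mean(np.abs(field.data) ** 2))
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    sigma = math.sqrt(p_noise / 2.0)
    noise = sigma * (
        rng.standard_normal(field.data.shape) + 1j * rng.standard_normal(field.data.shape)
    )
    return WaveField(
        data=field.data + noise,
        voxel_spacing_mm=field.voxel_spacing_mm,
        frequency_hz=field.frequency_hz,
        mask=field.mask,
        ground_truth_k_map=field.ground_truth_k_map,
    )
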