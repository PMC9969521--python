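"""Model/Results interface for reverberant elastography.

:class:`ReverberantElastography` wraps a complex wave field together with
the reconstruction options; :meth:`~ReverberantElastography.fit` runs the
phase-gradient inversion and returns an :class:`ElastogramResults` carrying
the wavenumber, speed and modulus maps, summary statistics, reverberance
diagnostics and plotting helpers.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inversion import ElastogramSet, FilterSpec, KernelSpec, reconstruct
from .metrics import RegionStats, cnr_db, mean_error_pct, region_stats
from .reverberance import similarity_map
from .simulate import COMPONENTS, WaveField

__all__ = ["ReverberantElastography", "ElastogramResults"]


class ReverberantElastography:
    """Reverberant shear-wave elastography estimator for one wave field.

    Parameters
    ----------
    field : WaveField
        Complex 3-component harmonic displacement volume.
    kernel : KernelSpec, optional
        Plane-fit kernel geometry (default 6.4 mm, dense stride).
    filter_spec : FilterSpec, optional
        Spatial bandpass; defaults to c in [0.3, 3.5] m/s at the field's
        vibration frequency.
    A : float
        Wavenumber scaling constant (1 by default).
    density_kg_per_m3 : float
        Tissue density for mu = rho c^2 (default 1000, i.e. 1 g/cm^3).
    bandpass : bool
        Whether to apply the spatial bandpass before phase extraction.

    Examples
    --------
    >>> from revmre import SimulationConfig, simulate_reverberant_field
    >>> field = simulate_reverberant_field(SimulationConfig(rng_seed=7))
    >>> res = ReverberantElastography(field).fit()
    >>> 3000 < res.median_mu() < 5000
    True
    """

    def __init__(
        self,
        field: WaveField,
        kernel: Optional[KernelSpec] = None,
        filter_spec: Optional[FilterSpec] = None,
        A: float = 1.0,
        density_kg_per_m3: float = 1000.0,
        bandpass: bool = True,
        filter_mode: str = "slicewise",
        components: Sequence[str] = COMPONENTS,
    ):
        self.field = field
        self.kernel = kernel or KernelSpec()
        self.filter_spec = filter_spec or FilterSpec(frequency_hz=field.frequency_hz)
        self.A = A
        self.density_kg_per_m3 = density_kg_per_m3
        self.bandpass = bandpass
        self.filter_mode = filter_mode
        self.components = tuple(components)

    @classmethod
    def from_niftis(cls, in_dir, prefix: str = "wavefield", frequency_hz=None, **kwargs):
        """Build the model from NIfTI volumes on disk (see :mod:`revmre.io`)."""
        from .io import read_wavefield

        return cls(read_wavefield(in_dir, prefix, frequency_hz), **kwargs)

    def fit(self) -> "ElastogramResults":
        """Run the phase-gradient inversion and return the results object."""
        elastograms = reconstruct(
            self.field,
            kernel=self.kernel,
            filter_spec=self.filter_spec,
            A=self.A,
            density_kg_per_m3=self.density_kg_per_m3,
            bandpass=self.bandpass,
            filter_mode=self.filter_mode,
            components=self.components,
        )
        return ElastogramResults(self, elastograms)


class ElastogramResults:
    """Estimates produced by :meth:`ReverberantElastography.fit`."""

    def __init__(self, model: ReverberantElastography, elastograms: ElastogramSet):
        self.model = model
        self.elastograms = elastograms

    @property
    def composite_mu(self) -> np.ndarray:
        return self.elastograms.composite_mu

    def k(self, component: str) -> np.ndarray:
        return self.elastograms.k(component)

    def c(self, component: str) -> np.ndarray:
        return self.elastograms.c(component)

    def mu(self, component: str) -> np.ndarray:
        return self.elastograms.mu(component)

    def median_mu(self, component: Optional[str] = None) -> float:
        vol = self.composite_mu if component is None else self.mu(component)
        return float(np.nanmedian(vol))

    def region_stats(self, mask: np.ndarray, label: str = "") -> RegionStats:
        return region_stats(self.composite_mu, mask, label)

    def cnr_db(self, background_mask: np.ndarray, inclusion_mask: np.ndarray) -> float:
        return cnr_db(
            self.region_stats(background_mask, "background"),
            self.region_stats(inclusion_mask, "inclusion"),
        )

    def mean_error_pct(self, mu_reference_pa: float, mask: Optional[np.ndarray] = None) -> float:
        mu = (
            self.median_mu()
            if mask is None
            else self.region_stats(mask).mean_pa
        )
        return mean_error_pct(mu, mu_reference_pa)

    def similarity(self, window_voxels: int = 48, threshold_percent: float = 80.0, stride: int = 1):
        """Per-component similarity chi maps against the recovered wavenumber.

        The theoretical profile uses each component's median recovered
        wavenumber (the per-voxel estimates are too noisy to anchor the
        theoretical curve); pass a custom map to
        :func:`revmre.reverberance.similarity_map` for heterogeneous media.
        """
        out = {}
        for label in self.model.components:
            k_med = float(np.nanmedian(self.k(label)))
            k_map = np.full(self.model.field.grid_shape, k_med)
            out.update(
                similarity_map(
                    self.model.field,
                    k_map,
                    window_voxels=window_voxels,
                    threshold_percent=threshold_percent,
                    components=(label,),
                    stride=stride,
                )
            )
        return out

    def summary(self) -> str:
        """Human-readable summary table of the reconstruction."""
        rows = []
        for label in self.model.components:
            mu = self.mu(label)
            k = self.k(label)
            finite = np.isfinite(mu)
            rows.append(
                {
                    "component": label,
                    "median_k_rad_per_m": float(np.nanmedian(k)),
                    "median_c_m_per_s": float(np.nanmedian(self.c(label))),
                    "median_mu_pa": float(np.nanmedian(mu)),
                    "mu_iqr_pa": float(
                        np.subtract(*np.nanpercentile(mu, [75, 25]))
                    ),
                    "valid_voxels": int(finite.sum()),
                }
            )
        comp = self.composite_mu
        rows.append(
            {
                "component": "composite",
                "median_k_rad_per_m": np.nan,
                "median_c_m_per_s": np.nan,
                "median_mu_pa": float(np.nanmedian(comp)),
                "mu_iqr_pa": float(np.subtract(*np.nanpercentile(comp, [75, 25]))),
                "valid_voxels": int(np.isfinite(comp).sum()),
            }
        )
        table = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:.4g}")
        prov = self.elastograms.provenance
        header = (
            "Reverberant shear-wave elastography results\n"
            f"frequency: {self.elastograms.frequency_hz:g} Hz, "
            f"kernel: {prov.get('kernel_size_mm', '?')} mm "
            f"{tuple(prov.get('kernel_size_voxels', ()))} voxels, "
            f"A = {self.elastograms.scaling_constant_A:g}, "
            f"density = {self.elastograms.density_kg_per_m3:g} kg/m^3\n"
        )
        return header + table

    def plot(self, slice_index: Optional[int] = None, ax=None):
        """Show the central (or chosen) axial slice of the composite elastogram."""
        import matplotlib.pyplot as plt

        vol = self.composite_mu
        if slice_index is None:
            slice_index = vol.shape[2] // 2
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(vol[:, :, slice_index].T, origin="lower", cmap="viridis")
        ax.set_title(f"composite shear modulus (Pa), slice z={slice_index}")
        ax.set_xlabel("x (voxels)")
        ax.set_ylabel("y (voxels)")
        plt.colorbar(im, ax=ax, label="Pa")
        return ax
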