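import numpy as np
import pytest

import revmre as rv
from revmre.inversion import KernelSpec, estimate_wavenumber_map, fit_phase_plane
from revmre.preprocess import PhaseVolume


def _kernel_coords(n=4, spacing=1.0):
    o = (np.arange(n) - (n - 1) / 2.0) * spacing
    return np.stack(np.meshgrid(o, o, o, indexing="ij"), axis=-1).reshape(-1, 3)


class TestFitPhasePlane:
    def test_exact_plane(self):
        coords = _kernel_coords()
        phi = 3.0 * coords[:, 0] + 4.0 * coords[:, 1] + 0.0 * coords[:, 2] + 1.0
        kx, ky, kz, c0 = fit_phase_plane(phi, coords)
        assert np.allclose([kx, ky, kz, c0], [3.0, 4.0, 0.0, 1.0], atol=1e-10)

    def test_noisy_plane_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        coords = _kernel_coords()
        phi = 3.0 * coords[:, 0] + 4.0 * coords[:, 1] + 1.0 + rng.normal(0, 0.01, len(coords))
        got = np.array(fit_phase_plane(phi, coords))
        design = np.column_stack([coords, np.ones(len(coords))])
        oracle = np.linalg.solve(design.T @ design, design.T @ phi)
        assert np.max(np.abs(got - oracle)) < 1e-8

    def test_mostly_nan_kernel_flagged(self):
        coords = _kernel_coords()
        phi = np.full(len(coords), np.nan)
        phi[:6] = 1.0  # ~9% valid
        out = fit_phase_plane(phi, coords)
        assert all(np.isnan(v) for v in out)

    def test_degenerate_geometry_rejected(self):
        coords = _kernel_coords()
        coords[:, 2] = 0.0  # all voxels coplanar
        phi = coords[:, 0].copy()
        with pytest.raises(ValueError, match="rank"):
            fit_phase_plane(phi, coords)


@pytest.fixture(scope="module")
def plane_phase():
    # k chosen so mu = rho c^2 = 3340 Pa at 50 Hz: k = 2*pi*50*sqrt(1000/3340)
    k_true = 2 * np.pi * 50.0 * np.sqrt(1000.0 / 3340.0)
    cfg = rv.SimulationConfig(
        grid_shape=(20, 20, 20),
        n_sources=1,
        rng_seed=2,
        true_speed_m_per_s=2 * np.pi * 50.0 / k_true,
    )
    field = rv.simulate_reverberant_field(cfg)
    return k_true, rv.unwrap_phase(rv.component_phase(field, "X"))


class TestEstimateWavenumberMap:
    def test_plane_wave_recovery(self, plane_phase):
        k_true, phase = plane_phase
        kmap = estimate_wavenumber_map(phase, KernelSpec())
        interior = kmap[3:-3, 3:-3, 3:-3]
        assert np.nanmax(np.abs(interior - k_true)) / k_true < 1e-6

    def test_scaling_constant(self, plane_phase):
        k_true, phase = plane_phase
        k1 = estimate_wavenumber_map(phase, KernelSpec(), A=1.0)
        k4 = estimate_wavenumber_map(phase, KernelSpec(), A=4.0)
        ratio = k4[4:-4, 4:-4, 4:-4] / k1[4:-4, 4:-4, 4:-4]
        assert np.allclose(ratio[np.isfinite(ratio)], 2.0, atol=1e-9)

    def test_reverberant_recovery_within_ten_percent(self, reverberant_field):
        cfg, field = reverberant_field
        phase = rv.unwrap_phase(rv.component_phase(field, "X"))
        kmap = estimate_wavenumber_map(phase, KernelSpec())
        assert abs(np.nanmedian(kmap) - cfg.wavenumber_rad_per_m) / cfg.wavenumber_rad_per_m < 0.10

    def test_kernel_larger_than_volume_rejected(self):
        phase = PhaseVolume(np.zeros((8, 8, 8)), "X", False, (1.6, 1.6, 1.6))
        with pytest.raises(ValueError, match="larger"):
            estimate_wavenumber_map(phase, KernelSpec(size_mm=100.0))


class TestUnitConversions:
    def test_wavenumber_to_speed(self):
        assert rv.wavenumber_to_speed(2 * np.pi * 50.0, 50.0) == pytest.approx(1.0, abs=1e-12)
        assert rv.wavenumber_to_speed(157.0796, 50.0) == pytest.approx(2.0, rel=1e-6)
        assert np.isnan(rv.wavenumber_to_speed(np.nan, 50.0))

    def test_nonpositive_wavenumber_warns(self):
        with pytest.warns(RuntimeWarning, match="nonpositive"):
            out = rv.wavenumber_to_speed(np.array([-1.0, 100.0]), 50.0)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_speed_to_modulus(self):
        assert rv.speed_to_modulus(2.0) == pytest.approx(4000.0, abs=1e-10)
        assert rv.speed_to_modulus(np.sqrt(3340.0 / 1000.0)) == pytest.approx(3340.0, rel=1e-12)
        assert rv.speed_to_modulus(0.0) == 0.0
        with pytest.raises(ValueError):
            rv.speed_to_modulus(1.0, density_kg_per_m3=-5.0)


class TestCompositeElastogram:
    def test_idempotent_on_identical_maps(self):
        m = np.full((4, 4, 4), 1234.5)
        assert np.array_equal(rv.composite_elastogram(m, m, m), m)

    def test_mean_and_nan_skipping(self):
        a = np.full((2, 2, 2), 1000.0)
        b = np.full((2, 2, 2), 2000.0)
        c = np.full((2, 2, 2), 3000.0)
        assert np.all(rv.composite_elastogram(a, b, c) == 2000.0)
        b[...] = np.nan
        assert np.all(rv.composite_elastogram(a, b, c) == 2000.0)

    def test_all_nan_stays_nan(self):
        n = np.full((2, 2, 2), np.nan)
        assert np.all(np.isnan(rv.composite_elastogram(n, n, n)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            rv.composite_elastogram(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)), np.zeros((2, 2, 2)))


class TestReconstruct:
    def test_single_plane_wave_exact(self, plane_wave_field):
        cfg, field = plane_wave_field
        mu_true = 1000.0 * (2 * np.pi * 50.0 / cfg.wavenumber_rad_per_m) ** 2
        res = rv.reconstruct(field, bandpass=False)
        interior = res.composite_mu[3:-3, 3:-3, 3:-3]
        assert np.nanmax(np.abs(interior - mu_true)) / mu_true < 1e-4

    def test_chain_consistency(self, reverberant_field):
        """Stored maps satisfy c = 2*pi*f/k and mu = rho c^2 exactly."""
        _, field = reverberant_field
        res = rv.reconstruct(field)
        for label in ("X", "Y", "Z"):
            k, c, mu = res.k(label), res.c(label), res.mu(label)
            ok = np.isfinite(k)
            assert np.allclose(c[ok], 2 * np.pi * 50.0 / k[ok], rtol=1e-12)
            assert np.allclose(mu[ok], 1000.0 * c[ok] ** 2, rtol=1e-12)
        finite = np.isfinite(res.per_component["X"]["mu"])
        recomposed = rv.composite_elastogram(
            res.mu("X"), res.mu("Y"), res.mu("Z")
        )
        assert np.allclose(
            recomposed[finite], res.composite_mu[finite], rtol=1e-12, equal_nan=True
        )

    def test_scaling_law(self, reverberant_field):
        """A -> s^2 A scales k by s, c by 1/s, mu by 1/s^2."""
        _, field = reverberant_field
        r1 = rv.reconstruct(field, A=1.0, components=("X",))
        r4 = rv.reconstruct(field, A=4.0, components=("X",))
        ok = np.isfinite(r1.k("X")) & np.isfinite(r4.k("X")) & (r1.k("X") > 0)
        assert np.allclose(r4.k("X")[ok], 2 * r1.k("X")[ok], rtol=1e-9)
        assert np.allclose(r4.c("X")[ok], r1.c("X")[ok] / 2, rtol=1e-9)
        assert np.allclose(r4.mu("X")[ok], r1.mu("X")[ok] / 4, rtol=1e-9)

    def test_phantom_contrast_direction(self):
        """Stiff inclusion reconstructs stiffer than the background.

        The inclusion spans several plane-fit kernels (40 mm) so its
        interior statistics are not dominated by interface artifacts.
        """
        cfg = rv.SimulationConfig(grid_shape=(64, 64, 64), rng_seed=4)
        spec = rv.PhantomSpec(
            background_modulus_pa=3340.0,
            inclusions=[((51.2, 51.2, 51.2), 40.0, 8150.0)],
        )
        field = rv.make_piecewise_phantom_field(spec, cfg)
        res = rv.reconstruct(field)
        incl = field.ground_truth_k_map < np.max(field.ground_truth_k_map)
        # erode ROIs away from the interface and volume border
        from scipy import ndimage

        incl_roi = ndimage.binary_erosion(incl, iterations=2)
        bg_roi = ~ndimage.binary_dilation(incl, iterations=4)
        bg_roi[:6] = bg_roi[-6:] = False
        bg_roi[:, :6] = bg_roi[:, -6:] = False
        bg_roi[:, :, :6] = bg_roi[:, :, -6:] = False
        mu_incl = np.nanmedian(res.composite_mu[incl_roi])
        mu_bg = np.nanmedian(res.composite_mu[bg_roi])
        assert mu_incl > mu_bg

    def test_stage_labels_in_errors(self, plane_wave_field):
        _, field = plane_wave_field
        with pytest.raises(RuntimeError, match=r"\[wavenumber/X\]"):
            rv.reconstruct(field, kernel=KernelSpec(size_mm=1000.0), bandpass=False)
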