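import numpy as np
import pytest

import revmre as rv
from revmre.reverberance import (
    AutocorrProfile,
    _autocorr2d_fft,
    measured_autocorrelation,
    measured_autocorrelation_2d,
)
from tests.conftest import oblique_plane_wave


def brute_force_autocorr2d(window):
    """O(n^4) linear autocorrelation oracle: B(d) = sum v(p+d) conj(v(p))."""
    n0, n1 = window.shape
    out = np.zeros((2 * n0 - 1, 2 * n1 - 1), dtype=complex)
    for di in range(-(n0 - 1), n0):
        for dj in range(-(n1 - 1), n1):
            acc = 0.0 + 0.0j
            for i in range(max(0, -di), min(n0, n0 - di)):
                for j in range(max(0, -dj), min(n1, n1 - dj)):
                    acc += window[i + di, j + dj] * np.conj(window[i, j])
            out[di + n0 - 1, dj + n1 - 1] = acc
    return out


class TestTheoreticalAutocorrelation:
    def test_lag_zero_limit_is_beta_over_three(self):
        prof = rv.theoretical_autocorrelation(100.0, [0.0, 0.01], beta=3.0, normalized=False)
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)  # beta/3

    def test_normalized_peak(self):
        prof = rv.theoretical_autocorrelation(100.0, np.linspace(0, 0.05, 20))
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_first_zero_crossing_matches_bisection_oracle(self):
        """Root of j0(x) - j1(x)/x located independently by bisection."""
        def bracket(x):
            return np.sin(x) / x - (np.sin(x) / x**2 - np.cos(x) / x) / x

        lo, hi = 2.0, 3.5
        for _ in range(80):
            mid = (lo + hi) / 2
            if bracket(lo) * bracket(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert rv.first_zero_crossing_kdr() == pytest.approx(lo, abs=1e-9)
        assert lo == pytest.approx(2.74, abs=0.01)

    def test_nonpositive_wavenumber_rejected(self):
        with pytest.raises(ValueError):
            rv.theoretical_autocorrelation(-5.0, [0.0, 0.01])


class TestMeasuredAutocorrelation:
    def test_fft_equals_brute_force(self):
        rng = np.random.default_rng(3)
        win = rng.standard_normal((12, 12)) + 1j * rng.standard_normal((12, 12))
        fast = _autocorr2d_fft(win)
        slow = brute_force_autocorr2d(win)
        assert np.max(np.abs(fast - slow)) < 1e-10

    def test_constant_field_profile_is_one(self):
        vol = np.ones((20, 20, 3), dtype=complex)
        prof = measured_autocorrelation(vol, (10, 10, 1), 16, 2, (1.0, 1.0, 1.0))
        assert np.allclose(prof.values[: 8], 1.0, atol=1e-9)

    def test_plane_wave_profile_matches_oracle(self):
        """Radial profile of a transverse plane wave vs the brute-force oracle."""
        k = 600.0
        vol = oblique_plane_wave((16, 16, 3), k, spacing_mm=1.6, direction=(1, 1, 0))
        prof = measured_autocorrelation(vol, (8, 8, 1), 16, 2, (1.6, 1.6, 1.6))
        slow = np.real(brute_force_autocorr2d(vol[:, :, 1]))
        counts = (16 - np.abs(np.arange(31) - 15))[:, None] * (
            16 - np.abs(np.arange(31) - 15)
        )[None, :]
        slow = slow / counts  # unbiased per-lag mean, as in the implementation
        c0 = 15, 15
        # identical radial binning applied to the oracle matrix
        di = np.arange(31)[:, None] - c0[0]
        dj = np.arange(31)[None, :] - c0[1]
        rbin = np.rint(np.sqrt(di**2 + dj**2)).astype(int)
        expected = np.array(
            [slow[rbin == b].mean() for b in range(16)]
        )
        expected /= expected[0]
        assert np.allclose(prof.values, expected, atol=1e-10)

    def test_white_noise_decorrelates(self):
        """Noise-only windows: negligible correlation beyond small lags."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vol = (rng.standard_normal((33, 33, 1)) + 1j * rng.standard_normal((33, 33, 1)))
            prof = measured_autocorrelation(vol, (16, 16, 0), 32, 2, (1.0, 1.0, 1.0))
            assert np.all(np.abs(prof.values[3:17]) < 0.2)

    def test_window_exceeding_volume_rejected(self):
        vol = np.ones((10, 10, 3), dtype=complex)
        with pytest.raises(ValueError, match="window"):
            measured_autocorrelation(vol, (5, 5, 1), 16, 2, (1.0, 1.0, 1.0))


class TestSimilarity:
    def _profile(self, values):
        lags = np.arange(len(values)) * 1e-3
        return AutocorrProfile(lags, np.asarray(values, float), True, "measured")

    def test_identical_profiles_score_100(self):
        p = rv.theoretical_autocorrelation(150.0, np.arange(10) * 1e-3)
        assert rv.similarity(p, p) == 100.0

    def test_constant_offset_scores_90(self):
        """RMSE of a uniform 0.1 offset is 0.1, so chi = 90%."""
        lags = np.arange(10) * 1e-3
        theo = rv.theoretical_autocorrelation(150.0, lags)
        shifted = AutocorrProfile(lags, theo.values.copy(), True, "measured")
        shifted.values = theo.values + 0.1  # post-init, keeps the normalized flag
        assert rv.similarity(shifted, theo) == pytest.approx(90.0, abs=1e-9)

    def test_large_error_clips_to_zero(self):
        lags = np.arange(10) * 1e-3
        a = AutocorrProfile(lags, np.r_[1.0, np.full(9, 2.5)], True, "measured")
        b = rv.theoretical_autocorrelation(150.0, lags)
        assert rv.similarity(a, b) == 0.0

    def test_mismatched_lag_grids_rejected(self):
        a = rv.theoretical_autocorrelation(150.0, np.arange(10) * 1e-3)
        b = rv.theoretical_autocorrelation(150.0, np.arange(10) * 2e-3)
        with pytest.raises(ValueError, match="lag grid"):
            rv.similarity(a, b)


class TestSimilarityMap:
    def test_directed_field_scores_low(self):
        """A single plane wave is directed: chi mostly below threshold."""
        vol = oblique_plane_wave((48, 48, 48), 157.0, direction=(1, 0.2, 0.1))
        field = rv.WaveField(
            data=np.stack([vol, vol, vol]), voxel_spacing_mm=1.6, frequency_hz=50.0
        )
        k_map = np.full((48, 48, 48), 157.0)
        maps = rv.similarity_map(field, k_map, window_voxels=48, components=("X",), stride=8)
        chi = maps["X"].chi_percent
        assert np.isfinite(chi).any()
        assert maps["X"].reverberant_percent < 50.0

    def test_reverberant_field_scores_high(self):
        cfg = rv.SimulationConfig(grid_shape=(64, 64, 64), rng_seed=6)
        field = rv.simulate_reverberant_field(cfg)
        maps = rv.similarity_map(
            field, field.ground_truth_k_map, window_voxels=48, components=("X",), stride=8
        )
        chi = maps["X"].chi_percent
        assert np.nanmean(chi) > 75.0

    def test_zero_field_yields_nan(self):
        field = rv.WaveField(
            data=np.zeros((3, 48, 48, 48), dtype=complex),
            voxel_spacing_mm=1.6,
            frequency_hz=50.0,
        )
        k_map = np.full((48, 48, 48), 157.0)
        maps = rv.similarity_map(field, k_map, window_voxels=48, components=("X",), stride=16)
        assert not np.isfinite(maps["X"].chi_percent).any()
        assert maps["X"].reverberant_percent == 0.0

    def test_window_larger_than_volume_rejected(self, plane_wave_field):
        _, field = plane_wave_field
        with pytest.raises(ValueError, match="window"):
            rv.similarity_map(field, field.ground_truth_k_map, window_voxels=64)


class TestPlateauExperiment:
    def test_single_row_degenerate_list(self):
        cfg = rv.SimulationConfig(grid_shape=(48, 48, 48), rng_seed=0)
        tab = rv.plateau_experiment(cfg, n_sources_list=[20], seeds=[0])
        assert len(tab) == 1 and tab.loc[0, "n_sources"] == 20

    def test_nonincreasing_list_rejected(self):
        cfg = rv.SimulationConfig(grid_shape=(48, 48, 48), rng_seed=0)
        with pytest.raises(ValueError, match="increasing"):
            rv.plateau_experiment(cfg, n_sources_list=[10, 10])


class TestFitKFromAutocorrelation:
    def test_self_consistency(self):
        k = 172.0
        lags = np.arange(0, 20) * 1.6e-3
        prof = rv.theoretical_autocorrelation(k, lags)
        prof = AutocorrProfile(prof.lags_m, prof.values, True, "measured")
        assert rv.fit_k_from_autocorrelation(prof, (100.0, 300.0)) == pytest.approx(k, rel=1e-3)

    def test_agrees_with_phase_gradient_on_reverberant_windows(self):
        """Both estimators track one wavenumber; aggregates agree within 10%."""
        fits, pgs = [], []
        for seed in (11, 21, 31):
            cfg = rv.SimulationConfig(grid_shape=(64, 64, 64), rng_seed=seed)
            field = rv.simulate_reverberant_field(cfg)
            prof = measured_autocorrelation(
                field.component("X"), (32, 32, 32), 32, 0, field.voxel_spacing_mm
            )
            fits.append(rv.fit_k_from_autocorrelation(prof, (60.0, 400.0)))
            sub = rv.WaveField(
                data=field.data[:, 16:48, 16:48, 16:48],
                voxel_spacing_mm=field.voxel_spacing_mm,
                frequency_hz=field.frequency_hz,
            )
            phase = rv.unwrap_phase(rv.component_phase(sub, "X"))
            pgs.append(float(np.nanmedian(rv.estimate_wavenumber_map(phase, rv.KernelSpec()))))
        assert abs(np.mean(fits) - np.mean(pgs)) / np.mean(pgs) < 0.10

    def test_bounds_excluding_truth_rejected(self):
        k = 172.0
        lags = np.arange(0, 20) * 1.6e-3
        prof = rv.theoretical_autocorrelation(k, lags)
        prof = AutocorrProfile(prof.lags_m, prof.values, True, "measured")
        with pytest.raises(ValueError):
            rv.fit_k_from_autocorrelation(prof, (400.0, 900.0))


class TestCalibrateA:
    def test_single_plane_wave_gives_exactly_one(self, plane_wave_field):
        _, field = plane_wave_field
        assert rv.calibrate_A(field) == pytest.approx(1.0, abs=1e-9)

    def test_missing_ground_truth_rejected(self):
        field = rv.WaveField(
            data=np.ones((3, 8, 8, 8), dtype=complex),
            voxel_spacing_mm=1.6,
            frequency_hz=50.0,
        )
        with pytest.raises(ValueError, match="ground_truth"):
            rv.calibrate_A(field)
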