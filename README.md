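# revmre — reverberant shear-wave MR elastography

`revmre` is a toolkit for **magnetic resonance elastography (MRE)** with
**reverberant shear-wave fields**: the complex wave patterns that arise when
harmonic shear waves from a mechanical driver reflect off the many internal
surfaces of a constrained organ (brain, or a brain-shaped phantom) and
superimpose from many directions.  Instead of fighting reflections, the
reverberant approach embraces them: a statistically isotropic superposition
of plane shear waves has simple local statistics from which tissue stiffness
can be estimated quickly and locally.

It is aimed at MRE researchers who want a self-contained, testable
implementation of the reverberant pipeline — including a synthetic wave-field
generator with known ground truth, so every stage can be validated without
scanner data.

## The model

A reverberant field is modelled as a superposition of plane shear waves,

```
V(r) = Σ_q  n̂_q v_q exp(i (k d̂_q·r + θ_q)),      k = 2πf / c,
```

with propagation directions `d̂_q` uniform on the sphere, transverse
polarizations `n̂_q ⊥ d̂_q`, and random phases `θ_q`.  The toolkit implements:

- **Phase-gradient inversion.** Writing the field in ersatz form
  `ν(r) = V₀ e^{iφ(r)}`, the local wavenumber obeys
  `k² = A (k_x² + k_y² + k_z²)` where `(k_x, k_y, k_z)` is the slope of a
  plane fitted (SVD least squares) to the unwrapped phase in overlapping
  6.4 mm kernels, and `A = 1`.  Shear speed and modulus follow from
  `c = 2πf/k` and `μ = ρc²` (ρ = 1 g/cm³); per-component modulus maps are
  averaged voxelwise into a composite elastogram.
- **Reverberance quantification.** For an isotropic field the 2D
  autocorrelation of one displacement component over its transverse plane is
  `B(Δr) = (β/2)[j₀(kΔr) − j₁(kΔr)/(kΔr)]` (spherical Bessel functions).
  The similarity statistic `χ(%) = (1 − RMSE) × 100` between the measured
  windowed autocorrelation and this theoretical surface quantifies how
  reverberant the data are; voxels with `χ > 80%` are classified reverberant.
- **Preprocessing.** Temporal Fourier extraction of the complex harmonic
  motion from ≥3 phase-offset snapshots, an annular spatial bandpass with
  speed-derived cutoffs (`k_l = 2πf/c_h`, `k_h = 2πf/c_l`; defaults
  c_l = 0.3 m/s, c_h = 3.5 m/s), and reliability-ordered 2D phase
  unwrapping with inter-slice alignment.
- **Evaluation metrics.** Contrast-to-noise ratio
  `CNR(dB) = 20 log₁₀(2(μ_b−μ_i)²/(σ_b²+σ_i²))`, signed mean error
  `ME(%) = (μ_e−μ_ref)/μ_ref × 100`, and the Young-to-shear conversion
  `μ = E/(2(1+ν))` with ν = 0.495 for gelatin/soft tissue.

## Worked example

Simulate a fully reverberant field (100 incident waves, 64³ voxels at
1.6 mm, 50 Hz vibration, true speed 2 m/s so μ = 4000 Pa), fit the model,
and inspect the results:

```python
import revmre as rv

cfg = rv.SimulationConfig(grid_shape=(64, 64, 64), voxel_spacing_mm=1.6,
                          frequency_hz=50.0, true_speed_m_per_s=2.0,
                          n_sources=100, rng_seed=7)
field = rv.simulate_reverberant_field(cfg)
res = rv.ReverberantElastography(field).fit()
print(res.summary())
```

```
Reverberant shear-wave elastography results
frequency: 50 Hz, kernel: 6.4 mm (4, 4, 4) voxels, A = 1, density = 1000 kg/m^3
component  median_k_rad_per_m  median_c_m_per_s  median_mu_pa  mu_iqr_pa  valid_voxels
        X                 170             1.848          3414  1.096e+04        226981
        Y               225.4             1.394          1942  1.035e+04        226981
        Z               190.2             1.652          2728  1.135e+04        226981
composite                 NaN               NaN          6266  1.166e+04        226981
```

The true wavenumber is 157 rad/m.  Component X tracks it well (170 rad/m,
median μ 3414 Pa vs 4000 Pa true); component Y is inflated by phase-unwrap
tears (225 rad/m).  The wide interquartile ranges are characteristic of
per-voxel phase-gradient estimates in fully developed speckle, and the
voxelwise-mean composite inherits their heavy upper tail (see
`docs/methods.md`).  The reverberance diagnostic flags exactly the
unreliable component:

```python
maps = res.similarity(window_voxels=48, stride=8)
for label, smap in maps.items():
    print(label, f"{smap.reverberant_percent:.1f}% reverberant")
```

```
X 86.1% reverberant
Y 0.0% reverberant
Z 48.6% reverberant
```

The same pipeline runs from the shell:

```sh
revmre simulate --out sim/ --grid 64 --n-sources 100 --seed 7
revmre invert --in sim/ --out maps/
revmre plateau --out plateau.csv --grid 96 --seeds 10
```

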