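# Methods

This note records the models, estimators, numerical choices and known
limitations of `revmre`, in the package's own words.

## Wave-field model and simulator

The simulator (`revmre.simulate`) synthesizes the complex harmonic
displacement of a reverberant shear-wave field as a finite superposition of
plane shear waves

    V(r) = Σ_q n̂_q v_q exp(i (k d̂_q·r + θ_q)),

all sharing one wavenumber `k = 2πf/c`.  Directions `d̂_q` are uniform on
the unit sphere (normalized Gaussian draws); polarizations `n̂_q` are unit
vectors drawn uniformly on the circle perpendicular to `d̂_q` (pure shear);
phases are uniform on `[0, 2π)`.  Amplitudes default to unit magnitude
(`amplitude_model="unit"`); a Rayleigh option (scaled so `E[v²] = 1`) adds
amplitude diversity.  With 10 sources the field is effectively directed;
with 100 it is statistically isotropic ("fully reverberant").  The
simulator produces displacement; particle velocity differs only by the
constant factor `iω₀`, which cancels in every wavenumber estimate.

Default study conditions: 48³–96³ grids, 1.6 mm isotropic voxels, 50 Hz
vibration, c = 2 m/s (μ = 4 kPa), 100 sources.  These match a soft-tissue
phantom imaged at typical MRE settings; the 2.5 mm / 70 Hz brain protocol
is reached by changing two parameters.

**Temporal sampling.** `sample_phase_offsets` produces
`Re{V e^{−i2πm/n}}` snapshots (n ≥ 3; four in practice), and
`extract_harmonic` inverts them with the fundamental DFT bin scaled by
`2/n`, so the round trip is exact to machine precision.

**Noise.** `add_noise` injects i.i.d. complex Gaussian noise scaled to a
field-wide SNR in dB.

**Inclusion phantom fixture.** `make_piecewise_phantom_field` builds a
piecewise-homogeneous medium (spherical inclusions in a background, with
`k = 2πf√(ρ/μ)` per region).  All regions share a single source set —
regions differ only in wavenumber, and each inclusion's waves are
phase-referenced at its center — and regions are cross-faded over ~1.5
voxels at the surface.  This keeps the stitched field slice-to-slice
coherent: a fully incoherent stitch leaves every slice's inclusion
cross-section free to unwrap with an arbitrary 2π offset, which destroys
through-slice gradients everywhere inside the inclusion (we measured
wavenumber medians an order of magnitude above truth before adopting the
coherent construction).  The fixture is geometric, not physical: there is
no refraction, mode conversion or standing-wave structure at interfaces,
so it tests estimator locality and contrast direction, not wave physics.
Interior statistics are meaningful for inclusions spanning several
plane-fit kernels (≥ ~25 mm at 1.6 mm voxels); at the 18 mm scale of real
phantom inclusions the interior (~700 voxels) remains interface-dominated.

## Preprocessing

**Bandpass.** The annular spatial filter passes radial wavenumbers in
`[k_l, k_h] = [2πf/c_h, 2πf/c_l]` (defaults c_l = 0.3, c_h = 3.5 m/s:
below c_l lies high-wavenumber noise, above c_h slow longitudinal bulk
motion maps to near-DC spatial frequencies).  Edges are raised-cosine
tapers of width 10% of each cutoff (hard edges ring).  The default
`slicewise` mode applies the 2D filter in each of the three orthogonal
slice orientations and averages; a single 3D radial annulus is available
as `mode="radial3d"`.  Note the printed cutoff formula in the source
literature contains a spurious factor; `k_l = 2πf/c_h` is the only
dimensionally consistent reading and is what is implemented.

**Phase extraction and unwrapping.** Each component's wrapped phase is its
complex argument in `(−π, π]`; voxels below 10⁻³ of the component's
99th-percentile magnitude are masked (their phase is noise).  Unwrapping
is 2D per axial slice with scikit-image's reliability-ordered algorithm,
followed by sequential inter-slice alignment by the integer multiple of 2π
that minimizes the median slice-to-slice jump.  A genuinely 3D unwrap is
deliberately *not* used: see "Why A = 1 works" below.

## Inversion

In each overlapping kernel (6.4 mm per side, `max(3, round(6.4/spacing))`
voxels, i.e. 4³ at 1.6 mm; dense stride 1) a plane
`φ ≈ k_x x + k_y y + k_z z + c₀` is fitted to the unwrapped phase by
SVD-backed least squares, and `k = √(A(k_x²+k_y²+k_z²))` with `A = 1`.
Kernels truncated by the volume or mask boundary yield NaN (no shrunken
fits); kernels with ≥ 80% finite voxels are fitted on the valid subset.
When every voxel is finite the centered normal matrix is diagonal, so the
dense map reduces to three correlations with fixed weight stencils — the
fast path.  `c = 2πf/k` and `μ = ρc²` (ρ defaults to 1000 kg/m³) hold
exactly between stored maps, and the composite elastogram is the voxelwise
mean of the per-component μ maps.

### Why A = 1 works — and what it hides

For a *single plane wave* the phase gradient magnitude equals k exactly,
and the whole chain is exact to 1e-6 (the analytic oracle in the tests).
For a *fully developed isotropic* field the per-voxel phase gradient is a
heavy-tailed ratio statistic (Student-t-like at field nulls): its point
median is only ≈ 0.75 k.  Slice-wise 2D unwrapping of a vortex-rich field
adds through-slice inconsistencies that inflate the z-gradient, and at
50 Hz / 1.6 mm the two effects roughly cancel: the median plane-fit k lands
within a few percent of truth with A = 1, which is precisely the regime in
which the empirical calibration `A ≈ 1` (verified by `calibrate_A`,
1 ± 0.15 over 20 seeds in the acceptance tests) holds.  A cleaner (3D)
unwrap removes the inflation and the median drops to ≈ 0.8 k — the
calibration and the unwrapping strategy are a package deal.

Two consequences are documented rather than hidden:

- the per-voxel μ distribution has a severe upper tail (small-k voxels map
  to huge moduli), so the voxelwise-mean composite's median sits well above
  the per-component medians on fully reverberant simulations (~ +70% at the
  default conditions).  Per-component medians are the robust summary;
- the tear density grows with wavenumber, so reconstructions of the same
  medium at 70 Hz are inflated more than at 50 Hz and the two disagree by
  ~35% on fully reverberant simulations.  Real, partially directed fields
  (the regime the method is used in, with similarity ≈ 80–90%) have far
  tighter gradient distributions.

## Reverberance statistics

The theoretical transverse-plane autocorrelation of one displacement
component is `B(Δr) = (β/2)[j₀(kΔr) − j₁(kΔr)/(kΔr)]`, with the removable
singularity at Δr = 0 evaluated by its limit (value β/3); normalized
profiles divide by that value.  The first zero crossing of the normalized
profile is at `kΔr ≈ 2.744`.

The measured autocorrelation of a window is computed through the
spatial-frequency power spectrum (Wiener–Khinchin), zero-padded so the
correlation is linear, and divided by the per-lag pair counts — the
unbiased per-lag mean, so a constant field autocorrelates to exactly 1 at
every lag.  Radial averaging into one-voxel lag bins gives the profile
used for display and for the autocorrelation-fit wavenumber cross-check.

The similarity statistic compares the **full 2D autocorrelation matrix**
(not its radial average) with the radially symmetric theoretical surface,
over lags inside the first theoretical zero crossing:
`χ = (1 − RMSE) × 100`, clipped to [0, 100].  The matrix form is essential:
a directed field's autocorrelation is strongly anisotropic, which the
matrix RMSE penalizes but radial averaging washes out entirely (measured:
radial-profile similarity is flat in the number of sources; matrix
similarity rises from ≈ 77% at 10 sources to ≈ 88% at 100).  Windows must
span about two shear wavelengths (default 48 voxels at the study
conditions) — sub-wavelength windows cannot distinguish directed from
reverberant structure.  Classification uses the strict rule χ > 80%; the
threshold sits at the knee of the similarity-versus-source-count curve
(steep rise from 10 to ~50 sources, plateau thereafter), which
`plateau_experiment` reproduces.

`fit_k_from_autocorrelation` least-squares fits the theoretical profile to
a measured radial profile (coarse grid scan over the bounds, then bounded
scalar refinement; lags restricted per candidate to its first zero
crossing).  On fully reverberant windows it agrees with the phase-gradient
median to ~10%; both carry ~8–9% single-window sampling noise, so
cross-estimator checks aggregate several windows.

`calibrate_A` reports `median(k_true²/(k_x²+k_y²+k_z²))` for fields with
known ground truth; it never changes A silently.

## Evaluation metrics

CNR uses population standard deviations (divide by n) within ROIs; zero
contrast returns −∞ with a warning rather than raising, so batch
evaluation never aborts.  Mean error is signed (negative =
underestimation).  `young_to_shear` excludes ν = 0.5 exactly.

## Numerical and interface choices

- Lengths are mm at API boundaries, wavenumbers rad/m, moduli Pa; reports
  echo kPa.  Conversions are centralized in the dataclasses.
- Complex volumes are stored as real/imaginary NIfTI pairs per component
  (with a single 5D-file option); frequency metadata lives in a JSON
  sidecar, and the sidecar also preserves float64 voxel spacing (NIfTI
  zooms are float32).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations give bit-identical
  fields.
- Problem sizes in the test-suite experiments (48³–96³ grids, 4–20 seeds)
  are chosen so each statistical check has adequate power while the whole
  suite stays desk-scale; the simulator is O(sources × voxels).

## Known limitations

- The phase-gradient estimator is analyzed and tested here on simulated
  fields only; scanner data additionally involve coil phase, motion-encoding
  efficiency and registration, which are out of scope.
- Fully reverberant simulations are the estimator's worst case (see "Why
  A = 1 works"); headline accuracy claims from partially directed real
  fields do not transfer to that regime, and the package reports the
  discrepancy honestly in its acceptance tests rather than masking it.
- The inclusion-phantom fixture does not model refraction or mode
  conversion and cannot validate sub-kernel-scale lesion detectability.
- No directional filtering, no finite-element comparator inversion, no
  DICOM ingestion, no registration or segmentation.
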