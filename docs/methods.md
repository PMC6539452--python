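# Methods

This note records the physical model, the numerical choices and the known
limitations of the package, in the order the pipeline uses them.

## System model

The scanner is modelled in-plane (2D, one axial slice). The incident beam
is a **parallel fan along +x** in laboratory coordinates; the rotation
stage turns the object about the world origin (45 views over 360° by
default), while source, pinhole and detector stay fixed. The real bench
uses a cone beam from a tube at finite distance, but at the ~75 mm-plus
source distances and 30–50 mm object sizes of interest the in-slice
divergence is a secondary effect, so the source-to-center distance does
not enter the model at all.

The collimator is an **ideal rectangular pinhole** (0.5 mm wide × 2 mm
high) at 75 mm from the rotation center, with a 256-pixel linear detector
(0.5 × 2 mm pixels) 63.5 mm behind it at 90° to the beam. A point emitter
projects through the aperture to a uniform spot of width w·(1 + L₂/L₁) on
the detector; each pixel receives the total aperture solid-angle fraction
A·cosχ/(4πd²) times its overlap with that spot. The 2 mm aperture/pixel
height is collapsed into that solid angle (no vertical clipping), and no
collimator penetration or depth-of-interaction is modelled. A Monte-Carlo
ray-sampling test validates the per-pixel solid angles to better than 1%.
With these defaults the object-plane field of view is
128 mm × 75/63.5 ≈ 151 mm, comfortably above the 50 mm object class the
bench targets.

## Photon physics

* **Spectra.** Two analytic models: monoenergetic, and Kramers
  bremsstrahlung I(E) ∝ (kVp − E)/E times Beer–Lambert transmission of a
  Cu filter (XFCT default 140 kVp + 0.4 mm Cu; transmission CT default
  65 kVp + 0.1 mm Cu), tabulated at 0.5 keV from 20 keV up. Tungsten
  characteristic lines and detector energy response are not modelled. The
  effective incident energy (fluence-weighted mean above the Gd K edge)
  of the default XFCT spectrum is ≈ 79 keV; a measured spectrum would be
  somewhat softer, but this energy only sets the entry-leg attenuation
  scale and its residual error is absorbed by the concentration
  calibration.
* **Attenuation.** Embedded mass-attenuation tables (water, PMMA,
  cortical bone, elemental Gd, Cu; 20–150 keV) transcribed from the
  public NIST tabulations, interpolated log-log and never across the Gd
  K edge (50.24 keV), where the table is split. NaGdF4 is synthesized as
  the stoichiometric mass-weighted mixture (Gd fraction 157.25/257.2 =
  0.611) of the Gd table and a water-like light-element matrix; at these
  energies the Na/F part is a sub-0.1% effect on any voxel below
  ~30 mg/mL.
* **Fluorescence.** Gd Kα doublet at 42.98/42.28 keV (2:1 intensities),
  K fluorescence yield ω_K = 0.93 (standard literature value; the
  absolute emission scale cancels in calibration). Kβ lines are ignored:
  they fall in the 45–51 keV side bin and would be treated as scatter by
  the acquisition scheme anyway. The excitation cross-section is the
  fluence-weighted Gd photoelectric μ/ρ above the K edge.
* **Compton scatter.** Klein–Nishina differential cross-section
  dσ/dθ (azimuthally integrated); the per-bin scatter weights integrate
  the *source* spectrum against it over each bin. Whether the spectrum in
  that integral should be the source spectrum or the object-hardened one
  is ambiguous in principle; the package uses the source spectrum, and the
  simulator makes the matching assumption (below), so the correction is
  self-consistent.

## Forward simulator

Single-scatter, ideal-detector transport. Per view the object maps are
resampled to the laboratory frame (bilinear), the entry-leg optical depth
is a cumulative sum along the beam axis, and the exit leg from every voxel
to the pinhole is integrated by 224-point midpoint sampling. Expected
counts are

* fluorescence (into the bin containing the Kα lines):
  Φ_K · τ̄_Gd · c · ω_K · V · e^(−D_in) · Ω · e^(−D_out),
* scatter (into every bin b):
  Φ · n_e · V · [r_b(θ)/2π sinθ] · 4πΩ · e^(−D_in) · e^(−D_out),

with Poisson sampling optional. Three deliberate simplifications keep the
simulator consistent with the side-bin correction model: a single
effective incident energy sets D_in for all channels; a single exit energy
(Kα1, 42.98 keV) sets D_out for fluorescence *and* all scatter bins (the
bins are adjacent, so per-bin attenuation differences are a common-scale
effect that cancels from the bin ratios); and scattered photons are booked
at their incident energy (the Compton shift at ~40 keV/90° is ~3 keV,
below the 6 keV bin width). The electron-density weight is the voxel mass
density (water-like Z/A). Because every voxel on a given pixel's
acceptance ray sees the pinhole along the same direction, the per-pixel
scatter angle of the correction is nearly exact, and on noiseless
simulations the corrected sinogram matches the pure-fluorescence channel
to ~10⁻⁷ relative.

The default `source_fluence` (2×10⁸ photons/mm²/s, 10 s per view) gives
peak fluorescence-bin counts of order 10³ per pixel-view on the default
calibration phantom — photon-starved, bench-like statistics; the
acceptance run uses 10⁹ for its high-statistics condition (peak ≥ 5000).
The transmission scan is the parallel-beam 2D analogue of the cone-beam CT
step: 180 views over 180°, 5×10⁴ photons per ray, log-transformed with
zero-count rays floored at one count and flagged.

## Phantoms

* **Calibration phantom**: PMMA cylinder (radius 25 mm, density 1.19)
  with six 4 mm-radius insertions of Gd solution on a 15 mm ring at
  {0, 2, 5, 10, 15, 20} mg/mL. The exact insertion concentrations of the
  physical phantom are not published as text; this set spans the same
  working range (stock ≈ 20 mg/mL) and brackets the reported
  detectability limits, and is user-overridable.
* **Mouse-like slices** (`liver`, `kidney`, `leg_tumor`): elliptical
  water body, one or two cortical-bone discs, and one or two radially
  tapered (parabolic) Gd hotspots whose default peaks follow the reported
  organ uptake (7.94 / 2.51 / 7.13 mg/mL); a seed jitters placement
  sub-millimetre.

Rasterization is antialiased (4×4 supersampling, area-weighted edges);
total Gd mass is conserved to <1%. What the synthetic phantoms do *not*
emulate: anatomical texture, off-slice scatter, detector charge sharing,
beam-hardening streaks, motion. Passing tests therefore demonstrate the
correctness and internal consistency of the correction/reconstruction
chain under the stated transport model, not performance on real detector
data.

## Reconstruction

* **System matrix.** Assembled per view as B_k·S_k, where S_k is the
  sparse bilinear rotation of the object image to the laboratory frame
  and B_k applies the per-voxel attenuation factors and pinhole response —
  the same discretization the simulator uses, so simulator and
  reconstructor agree up to the physics actually under test. Entries below
  10⁻⁸ of the maximum are dropped.
* **MLEM.** Multiplicative update, uniform positive start, 100 iterations
  by default with an optional early stop at relative image change <10⁻⁴
  (disabled in the acceptance run). The Poisson log-likelihood is recorded
  each iteration and is asserted non-decreasing in the tests;
  nonnegativity holds by construction; zero-sensitivity voxels are frozen
  at zero. The iteration count is a standard plateau choice for 45-view
  pinhole data — the bench procedure does not prescribe one.
* **Transmission FBP.** Ramp-filtered backprojection (scikit-image
  `iradon`), recovering a uniform disc's center value to ≲0.3% noiselessly.
* **Material decomposition.** Bone is thresholded at the midpoint between
  water and nominal cortical bone μ at the CT energy (the bench threshold
  is unpublished; the midpoint is the natural two-class separator). Soft
  tissue becomes water with a CT-derived water-equivalent density (this
  also absorbs PMMA, ~1.16 water-equivalent); bone voxels get a
  bone-equivalent density the same way. The Gd term comes from the
  attenuation-free first MLEM pass: with no calibration available, only
  voxels above a robust significance floor (median + 6×1.4826·MAD over
  the object) survive — so a Gd-free slice contributes no spurious Gd
  attenuation — and the surviving peak is pinned to the stock
  concentration (20 mg/mL); when a calibration slope exists it should be
  passed instead (`gd_scale`), which matters for low-uptake slices where
  peak-pinning would overstate the Gd attenuation term.
* **Outer loop.** One pass of decomposition → matrix → MLEM by default,
  mirroring the sequential bench procedure; `n_outer` can iterate it.

## Calibration and detectability

ROI means (disc ROIs at 0.7× the insertion radius, pooled background ring)
against known concentrations, ordinary least squares, r² = 1 − SS_res/SS_tot.
CNR = (mean_target − mean_background)/SD_background with the background
pooled over all background ROIs and sample SD (n−1); the exact CNR
convention of the bench study is unpublished, this is the standard
Rose-criterion form. The detectability limit inverts the least-squares
CNR-versus-concentration line at CNR = 4. Negative calibrated values are
preserved in saved arrays (clamping is display-only).

## Numerical notes and edge cases

* Ray tracing: exact Siddon-style traversal for the reference line
  integral (chord-length conservation to 10⁻⁹ relative); the vectorized
  exit-leg integrals use 224-point bilinear midpoint sampling, which
  tracks the exact traversal to ~1% on smooth maps and is identical
  between simulator and reconstructor by construction.
* MLEM guards: forward projections floored at 10⁻¹², negative corrected
  counts clamped to zero before reconstruction (Poisson fluctuation
  artifacts; MLEM requires nonnegative data).
* Scatter estimation requires strictly positive side-bin weights; a
  monoenergetic beam outside the side bins is rejected rather than
  silently producing an undefined correction.
* Sub-seeds for the XFCT and CT noise streams are spawned from the master
  seed, so changing the master seed changes noisy outputs but never
  noiseless expectations.

## Problem sizes

Default working resolution is a 128×128 grid at 0.5 mm with 45 views ×
256 pixels (the acceptance configuration; ~25 s end to end on one CPU).
The test suite exercises the same code paths at 48–128 grids and 1–45
views, chosen so the full suite stays fast while covering every operation
at working resolution at least once.

## Known limitations

Single-scatter transport only; no Rayleigh scattering; ideal energy bins
(no charge sharing — on real photon-counting detectors this is a major
scatter-leakage channel); ideal pinhole (no penetration, vignetting or
depth of interaction); parallel-beam excitation; 2D slices only (no
cone-beam/FDK 3D reconstruction); no dose model. The embedded attenuation
tables are coarse (8–16 energies per material) — adequate because both
simulator and reconstructor read the same tables, but an external-data
user should prefer a finer tabulation source.
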