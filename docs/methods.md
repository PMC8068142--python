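# Methods

This note documents the models implemented in `plifscan`, the conventions
and defaults behind them, and what the simulator-based validation does and
does not demonstrate.

## Instrument model and coordinate conventions

The rig is modeled as a square sensor imaging a 420 mm × 420 mm plane
through a laser sheet held at a fixed angle θ (default 45°) to the chamber
sidewall, with laser and camera translating together along the chamber's
long axis at constant speed. The image plane is treated as metrically
uniform: no lens distortion or perspective model is applied, and the 25 ms
exposure's motion blur (~2.5 mm at 100 mm/s) is ignored; frames are
associated with the platform position at exposure start.

Image coordinates: the origin pixel is the corner nearest the laser source,
where illumination is strongest; `m` runs along the sheet away from the
laser, `n` vertically. Both are *physical* offsets in mm of pixel centers
from the origin pixel center (pixel index × pixel pitch), which keeps the
illumination formula dimensionally coherent and lets `r0` be specified in
mm. The shear into chamber coordinates is

    m' = m cosθ,  n' = n,  p' = p + m cosθ,

generalizing the 45° case (where both factors are 1/√2). θ = 90° collapses
the x' projection and is rejected as degenerate. The platform folds back
reflectively at the track ends (triangle-wave motion), so forward and
reverse sweeps are both usable.

`r0`, the fan-origin-to-image-origin distance, is not a measured rig
constant; its default, 210/tan(30°) ≈ 363.7 mm, is the distance at which a
60° fan exactly spans the 420 mm plane. It is an explicit configuration
field and should be set from the actual optics when known.

## Denoising

Stage order is fixed: background subtraction → binning → wavelet denoising.

* Background: pixelwise mean of laser-on frames recorded before injection.
  Negative residuals after subtraction are clipped to zero (fluorescence
  counts cannot be negative).
* Binning: block mean (not sum), so corrected intensities stay on the
  sensor count scale for any bin factor. Default 4×4.
* Wavelet shrinkage: soft thresholding with δ = σ(0.3936 + 0.1829 log₂N)
  for N > 32 (else 0), σ = median|fᵢ|/0.6745. σ is estimated once from the
  finest-scale *diagonal* detail subband (the closest 2D analogue of the
  "unit-scale" coefficient vector in the 1D construction) and reused for
  every subband; N is the per-subband coefficient count. Both choices are
  overridable. The rule as printed is discontinuous at the N = 32/33 branch
  (δ jumps from 0 to ≈1.32σ); it is implemented as printed, not smoothed.
* Family and depth are free parameters; the default is db4 with
  min(4, decomposable depth) levels and symmetric boundary extension. The
  boundary dialect is echoed into the provenance sidecar.

## Illumination correction

P(m,n) = r₀/√((r₀+m)² + n²) is the *relative illumination* (≤ 1, weakening
away from the laser corner, anchored to exactly 1 at the origin pixel
center). Correction divides the measured frame by P — equivalently
multiplies by r/r₀ — because the physical goal is to compensate weaker
illumination far from the source. The 1/r arc-length falloff is purely
geometric; no attenuation term is folded into this map.

## Attenuation model

Detected-to-ideal ratio Sd/S = 10^(−(Aex+Aem)/2), with each absorbance
ε∫C(l)dl integrated by composite trapezoid (≥ 101 nodes for callable
profiles; exact for constants). The factor-of-2 average-path division is
implemented as the cited approximation, not re-derived. Extinction
coefficients for fluorescein at 450 nm / 500–600 nm are required inputs
with order-of-magnitude defaults (8e-5 and 4e-5 per (mg/L)·mm); all
quantitative claims instead anchor on a *measured* rate: back-solve total
absorbance A = −2 log₁₀(1 − rate), scale linearly in uniform concentration,
convert back. This reproduces a consistent rate triplet (≈2.87 / 3.81 /
4.74% at 0.3 / 0.4 / 0.5 mg/L) without knowing the absolute path lengths.
Distance curves set both optical paths equal to the quoted detection
distance, giving log-linear decay.

## Reconstruction

After the shear, the x' lattice of every frame column is already regular
with spacing dy·cosθ, so only z' requires assignment: each column drops
into its nearest z' voxel (spacing = platform advance per frame,
speed/frame rate), with multiply-hit voxels averaged. Linear two-neighbour
z' interpolation is available behind a flag but off by default. Voxels
never intersected by a sheet carry NaN — explicitly distinct from measured
zero — so downstream statistics are unbiased; the summary CSV reports the
occupied-voxel fraction. Windows are fixed-duration chunks
(round(rate·duration) frames, default 5 s = 60 frames); a trailing partial
window is dropped with a warning. Frames within a window are sorted by
position and treated as one quasi-static field; forward and reverse sweeps
are merged chronologically and windowed alike.

Hit-averaging preserves the *mean* intensity level (mean over measured
voxels ≈ mean over contributing frame pixels), which is the bookkeeping
invariant the tests assert; per-voxel sums are not conserved by averaging
and are not claimed.

A stationary platform degenerates to a single-slice volume (2D monitoring
mode) with a warning rather than an error.

## Forward simulator

The plume is a continuous point source near the chamber floor: puffs with
Gaussian profile (variance 2Dτ per axis), advected upward at the rise
velocity, superposed over the emission history by fixed-step midpoint
quadrature (step ≤ 0.1 s, configurable), with one mirror image per chamber
wall approximating reflective boundaries. Defaults: source at
(250, 30, 250) mm, D = 150 mm²/s, rise 10 mm/s, 50 s emission. This is
deliberately the simplest field with closed-form mass accounting that
reproduces the qualitative behaviour of bottom injection: lateral spread
near the floor and a rising concentration centroid. It contains **no
turbulence**, no polydisperse optics, no photobleaching, and the sheet is
infinitesimally thin; single-wall images under-count corner reflections
once the plume spans a large fraction of the chamber. Passing round trips
therefore validate the *processing chain's* geometry, radiometry and noise
behaviour — not the fidelity of any real plume.

Rendering samples the field on the oblique sheet (exploiting the per-axis
separability of each puff for speed), multiplies by P(m,n), optionally by
the two-path attenuation ratio (trapezoid-sampled along the in-sheet laser
path from the fan apex and the perpendicular camera path, with
outside-chamber segments contributing nothing), then adds the sensor model.
With no noise model the *ideal float frame* is returned — no offset, no
quantization — so flat-fielding round trips are exact to machine precision;
with a noise model, offset + optional shot-noise approximation (normal with
count-proportional variance, default off) + read noise are added and the
frame is quantized to integer counts in the 16-bit range. All noise is
seeded (per-frame keys derived from one seed), so identical inputs give
bit-identical frames.

## Validation problem sizes

Equation-level and geometry checks run at the full 2048-px/512-binned
configuration. Simulator round trips run on scaled-down sensors (64–128 px,
bin 1–4) with the same optics, kinematics, frame rate and window arithmetic
(360 frames, six 5 s windows for the plume-recovery check); the processing
chain is resolution-agnostic, so the scaled runs exercise identical code
paths at practical cost. The plume-recovery scan starts 20 s into a 60 s
injection so the field evolves slowly relative to the 5 s window — the
regime in which windowed reconstruction of a moving plume is meaningful.
Consecutive windows alternate sweep direction, which introduces a sub-mm
sampling parity in intensity centroids; the bottom-up rise is therefore
asserted between same-direction windows plus as an overall trend.

## Known limitations

* Relative concentration only; no radiometric calibration to mg/L.
* No attenuation correction of reconstructed volumes (shown ≤ 5% at the
  relevant concentrations, then neglected — by design).
* Nearest-voxel z' assignment limits axial resolution to the 8.33 mm sheet
  spacing; structures thinner than a sheet spacing alias.
* The quasi-static window assumption breaks for fields evolving faster
  than ~the 5 s window; early-injection transients reconstruct with visible
  sweep-direction bias.
* The simulator's plume is laminar and single-source; it cannot stand in
  for turbulent dispersion data.
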