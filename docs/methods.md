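# Methods

## Model

Scanline intensities are modelled as a zero-mean Gaussian process over
beam-native coordinates `(r, α)`: `r` is depth along the beam (units of
the sample pitch), `α` the across-beam coordinate (lateral distance for
parallel beams, angle in radians for diverging beams).  Before regression
both intensities and coordinates are standardized to zero mean and unit
variance; the kernel length scales are rescaled by the same per-axis
factors, so standardization affects numerical conditioning only, never the
model.  The zero-mean prior is exact in standardized intensity space.

The covariance is stationary and anisotropic: squared exponential or
Matérn (ν ∈ {1/2, 3/2, 5/2}, evaluated through the half-integer closed
forms, which are exact and finite at r = 0 where the Γ/Bessel form
degenerates).  ν = 3/2 is the default: it drops the unrealistically strong
smoothness assumption of the SE kernel while staying once-differentiable,
and it gave the most accurate reconstructions in our studies.  The general
Bessel form exists only as a test oracle.

Key hyperparameters, with defaults and units:

| parameter | meaning | default |
|---|---|---|
| σ² | signal variance (standardized intensity units) | 1 |
| l_r | along-beam length scale (beam-native length units) | k_N·Δr (heuristic) or fitted |
| l_α | across-beam length scale (length or radians) | Δα/3 (heuristic) or fitted |
| ν | Matérn smoothness | 3/2 |
| σn² | observation noise (standardized intensity units) | 2×10⁻³ parallel, 8×10⁻³ diverging |

The per-probe σn² values are the operating points for log-compressed data
from linear and phased-array probes respectively.

### Diverging beams and the 1/r rule

At depth r the physical spacing between adjacent diverging beams is r·Δα,
so a depth-independent *cartesian* correlation length corresponds to an
angular `l_α` falling like 1/r.  The implemented profile is anchored at
mid-depth, `l_α(r̄ᵢ) = (Δα/3)·(|r̄|/2)/r̄ᵢ`, so that at r̄ᵢ = |r̄|/2 it
reproduces the parallel-grid value Δα/3.  The typeset form of this rule is
ambiguous; the alternative grouping `(Δα/3)·|r̄|²/r̄ᵢ` is selectable
(`reading="squared"`) but rejected as the default because it does not
reduce to the parallel rule at mid-depth.  Since a depth-varying `l_α`
makes the observation covariance non-stationary, depth scaling is applied
only in the patched path: the obs–obs covariance of each window uses `l_α`
at the patch's center depth and each cross-covariance row uses the
target's own depth, which keeps every window's K symmetric PSD.  The
exact (unwindowed) path accepts stationary kernels only.

The first diverging sample is placed one sample pitch from the apex
(`depth_offset = Δr` by default) so the 1/r rule never divides by zero.

## Windowed (patched) regression

Targets are partitioned into patches (one beam interval × 4 sample rows by
default); each patch is regressed from a local observation window, and
each target belongs to exactly one patch — overlap enriches windows but
never averages predictions, so there are no seam artifacts and the
patched-vs-exact comparison is well defined.

The window size is read as a **one-dimensional along-beam extent**: a
window of size W holds the W sample rows nearest the patch's centroid
depth on the two nearest beams to either side.  We implemented the
alternative reading (W = total observation count, nearest in a
standardized anisotropic metric; available as `mode="nearest"`) and
compared both on the 64×412 diverging study: under the axial reading the
PSNR gain from enlarging the window beyond 15 is ~0.01 dB (a genuine
plateau, with the window-15 patched GP within 0.02 dB of the full exact
GP), whereas under the total-count reading PSNR still climbs ~0.15 dB from
window 15 to 29.  Only the axial reading exhibits the
"negligible gain beyond 15" behavior that motivates the default window of
15, so it is the default.

For a fixed grid and kernel the per-patch weight matrix
`K*ᵀ(K+σn²I)⁻¹`, the prior variance diagonal and the explained-variance
diagonal depend only on coordinates.  They are precomputed once
(`build_operators`) and applied to any number of frames
(`patched_predict`) without further factorizations — the apply path is
O(N·M) multiply–adds, verified in tests by a Cholesky call counter.
Intensity standardization is per window and happens at apply time: only
the window mean enters the prediction (the scale cancels in the mean and
multiplies the variance), which is what keeps the operators
intensity-independent.

## Numerical choices

* Solve path: Cholesky of (K + σn²I + jitter), two triangular solves;
  never an explicit inverse.  Jitter starts at 10⁻¹⁰·σ² and escalates ×10
  at most 6 times; failure raises with a conditioning report.  Large
  matrices are factorized in place to halve peak memory.
* Posterior variances that fall below zero by cancellation are clamped to
  0 after a −10⁻⁸·σ² tolerance check.
* Identical estimate and truth give PSNR = +inf, reported as a documented
  sentinel (occurs only in degenerate identity cells).
* Nearest-neighbor ties break to the lower sample index, then the lower
  beam index.  The cubic-spline baseline is the tensor-product
  interpolating spline with not-a-knot boundaries (scipy's
  `cubic_legacy`; the newer "cubic" method is a local approximant that is
  not node-exact).  Baselines clamp out-of-hull targets to the edge and
  flag them; metrics use unclipped interpolator output so spline overshoot
  is not masked, and display paths clip to [0, 1].
* Out-of-footprint raster pixels are flagged and excluded from metrics,
  never zero-filled.

## Length-scale selection

`optimize_length_scales` minimizes the held-out MSE of the patched-GP
reconstruction of a leave-N-out split over (l_r, l_α), subject to
positivity.  The landscape is smooth but flat near the optimum, so the
search is a bounded Nelder–Mead simplex in log-parameter space
(relative f-tolerance 10⁻³, iteration cap 200, default init at the grid
heuristic); the returned objective never exceeds the initial one.  On
matched-model phantoms the fit recovers the generating scales within ~20%
on average (5 seeds), and the fitted point beats its ×2/÷2 log-grid
neighborhood.

The closed-form heuristics (`l_α = Δα/3`, `l_r = k_N·Δr`, with
k_N = n_total/n_kept the scanline reduction factor, and Δα the spacing of
the beams actually used) are empirical fits to optimized values on two
in-vivo datasets; their constants are texture-specific.  On phantoms whose
correlation structure is known, the matched kernel outperforms the
heuristic — on new data, fit the scales rather than trusting Δα/3.

## Phantoms

Three textures, all deterministic per (spec, seed), intensities mapped
affinely to [0.05, 0.95]:

* `gp_draw` (default) — a stationary GP draw on the observation lattice
  with known kernel (default Matérn 3/2, l_r = 3Δr, l_α = 1.5Δα, σ² = 1)
  plus i.i.d. Gaussian noise at the per-probe operating variance.  Exact
  dense-Cholesky sampling up to 10⁴ lattice points; larger lattices use a
  circulant-embedding FFT sampler (exact up to clipping of slightly
  negative embedding eigenvalues; validated against the dense sampler in
  tests).  Default grids mirror the two probe setups: 256×793 parallel
  and 64×412 diverging.
* `layered_tissue` — depth-wise echogenicity bands with smoothstep
  transitions and optional multiplicative log-normal speckle (a cardiac
  cartoon: dark blood pools, bright muscle).
* `speckle` — a smooth low-frequency background modulated by
  multiplicative speckle (a soft-tissue texture cartoon).

What the phantoms do **not** emulate: RF-domain physics (point-spread
function, frequency-dependent attenuation, true Rayleigh speckle
statistics), log-compression nonlinearity, motion, or anatomy-specific
structure.  Consequently, passing studies demonstrate correctness of the
regression machinery and the expected statistical behavior under the
model's own assumptions (matched-model optimality, variance growth with
decimation and depth); they do not by themselves establish clinical image
quality, which depends on how well the kernel family fits real tissue
texture.

## Evaluation protocol

Leave-N-out: keep n of the N scanlines (as evenly spaced as integer
indices allow, always including the first and last beam; the kept-beam
positions are carried exactly, so paper-style counts like 13-of-64 with
non-uniform kept spacing are handled), interpolate back onto the full
lattice in beam-native coordinates, and score **held-out scanlines only**
— every interpolator is exact on kept lines, so whole-image scores would
dilute the comparison.  MAE/MSE/PSNR follow the standard definitions on
[0, 1] intensities; relative PSNR subtracts the per-column minimum, so the
worst method sits at 0 dB.  Variance maps are normalized by a single
global maximum across the compared set.

## Problem sizes

Test-suite studies run on grids from 2×4 up to 64×412; the windowed-vs-
exact comparison and the acceptance script use the full 64×412 diverging
grid (13 184 observations after decimation to 32 beams, 13 184 held-out
targets), with 5 phantom seeds and a 13-point window sweep.  Statistical
orderings use 10 seeds on 32×64 grids; length-scale recovery uses 5 seeds
on 32×96 grids.  These sizes make the whole suite run in a few minutes on
a single CPU while keeping the headline comparison at the full
phased-array grid size.

## Known limitations

* The exact (full) GP path supports stationary kernels only; depth-scaled
  kernels are available only through the patched path.
* The heuristic length-scale constants are untested across anatomy,
  depths and probes; treat them as initializations for the optimizer.
* Operator caches are keyed by a geometry/kernel/plan fingerprint and are
  platform-dependent binary artifacts, not an interchange format.
* Variance maps are posterior variances under the assumed kernel; they are
  calibrated only to the extent the kernel matches the data.
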