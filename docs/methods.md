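# Methods

This note documents the models, conventions, and numerical choices
behind `qsmtrend`, in the order data flows through the pipeline.

## Forward model

Tissue magnetic susceptibility χ (ppm) induces a fractional field
shift that is a convolution with the field of a unit dipole; in the
Fourier domain

    Φ̂(k) = D(k) · χ̂(k),      D(k) = 1/3 − k_z²/|k|²,

with k_z the frequency component along B₀ (array axis 2 by
convention).  D vanishes on the magic-angle cone k_z² = |k|²/3 and at
k = 0; we set D(0) = 0 explicitly, which means *no reconstruction can
recover the spatial mean of χ*.  All reconstructed maps are therefore
referenced to zero mean over their mask, and every comparison against
ground truth references the truth volume to the same mask mean.  This
referencing convention is the package-wide substitute for an anatomical
reference region (none is singled out).

The kernel uses the continuous-k expression evaluated on the discrete
FFT frequency grid (cycles/mm, anisotropic voxels honored).  Forward
simulation and every inversion algorithm share the identical kernel,
so recovery tests measure algorithmic behavior, not kernel mismatch.

Phase accrual: θ = 2π·f₀·TE·Φ·10⁻⁶ with f₀ = γ/2π·B₀,
γ/2π = 42.577 MHz/T (proton; configurable), B₀ = 9.4 T, TE = 13 ms by
default.  Noise is i.i.d. complex Gaussian added to the unit-magnitude
complex signal, with SNR defined as magnitude over per-channel σ.
The wrapped phase is the angle of the noisy signal, in (−π, π].

## Synthetic phantom

The generator emulates an ex vivo primate brain at desk scale: an
ellipsoidal "brain" mask (semi-axes 20 × 17 × 15 mm) on a 48³–96³ grid
of 1 mm voxels, containing four bilateral ellipsoidal nuclei placed so
that each lies strictly inside the mask eroded by the largest V-SHARP
radius, with no overlaps.  Nucleus susceptibility is uniform at
χ(age) = slope·age + intercept:

| nucleus | slope (ppm/yr) | intercept (ppm) |
|---------|----------------|-----------------|
| Cd      | 0.00300        | 0.00377         |
| Pt      | 0.00260        | 0.00246         |
| Gp      | 0.00452        | 0.00242         |
| Sn      | 0.00619        | −0.00216        |

In-mask background tissue is 0 ppm.  Two 2.5 mm spheres of +0.5 ppm
outside the mask provide a background field that dominates the
internal nucleus field near the brain surface.  The strength is chosen
for physical self-consistency at desk scale: 1 mm voxels are ~7×
coarser than the real ~150 µm acquisition, and stronger sources would
drive the in-brain per-voxel phase increment beyond π — spatial
aliasing that no unwrapping algorithm can undo and that a real
protocol avoids by using the minimum echo time.  At 0.5 ppm the
largest in-mask phase step is ≈1.2 rad.

`diamagnetic_fraction` flips that fraction of Gp and Sn voxels to
−|χ|, emulating the diamagnetic voxels observed in those nuclei ex
vivo (default 0).  The standard noisy acquisition uses SNR = 20,
representative of high-resolution ex vivo gradient echo; at that level
the reconstruction error near structures is dominated by cone-amplified
noise streaks, the artifact regime the algorithm comparison is about.
Criteria that are defined at SNR 50 (L-curve corner selection, the
round-trip accuracy band) use SNR 50.

What the phantom does **not** emulate: irregular nucleus shapes and
internal susceptibility gradients, partial-volume effects at nucleus
borders, B₀ inhomogeneity and chemical shift, coil sensitivity,
resolution anisotropy, and the fixation-dependent susceptibility of
real ex vivo tissue.  Passing recovery tests therefore demonstrate
correctness of the measurement chain under the stated generative
model, not accuracy on real specimens.

All randomness (noise, diamagnetic voxel choice, ROI jitter) descends
from one integer seed via `numpy` `SeedSequence` spawning; identical
(config, seed) reproduce results bit-for-bit.

## Phase unwrapping

The Laplacian estimate
u = ∇⁻²(cos θ ∇² sin θ − sin θ ∇² cos θ) is computed with the Fourier
multiplier −(2π|k|)²; the inverse Laplacian zeroes DC, and the output
is demeaned.  Two numerical refinements:

* **Mirror extension.**  The volume is extended by even symmetry
  before the FFTs.  A linear phase ramp is harmonic, hence invisible
  to a periodic Fourier Laplacian (for an exact-bin ramp the source
  term cancels identically); its even extension is a triangle wave
  whose restriction to the original box is the ramp, so ramps unwrap
  correctly.
* **Integer correction** (default on).  The continuous estimate u is
  snapped back onto the measurement: θ_unwrapped = θ + 2π·round((u −
  θ − c)/2π) + c, where c is the circular mean of u − θ (centering the
  rounding away from half-cycle boundaries).  Wherever u is within π
  of the true phase this makes unwrapping exact; the raw estimate
  alone smooths sharp field transitions at nucleus borders (≈7% rel.
  RMS at 64³) because the nonlinear identity behind it only holds to
  discretization order.  Disable with `integer_correction=False` to
  obtain the plain estimate.

## V-SHARP background removal

A field generated outside the mask is harmonic inside it, hence equal
to its spherical mean over any fully interior sphere.  For each sphere
radius r in the schedule (default 4, 3, 2, 1 mm) the filter
(δ − ρ_r) ⊛ θ is evaluated; each voxel keeps the result for the
largest radius whose sphere fits inside the mask.  The composite is
deconvolved by the largest-radius filter with truncated inversion
(spectrum magnitudes below `tsvd_threshold` = 0.05 are zeroed) and the
output is zeroed outside the mask eroded by the largest radius — the
only region where the tissue field is defined.

Measured accuracy at the standard 64³ phantom: external-source fields
are suppressed to <1% residual RMS inside the eroded mask, and the
recovered local field correlates with the internal-only ground truth
at ρ > 0.998.  The absolute rel. RMS error of the recovered internal
field is ≈5%, dominated by the mask-support truncation inherent to
single-kernel truncated deconvolution on a finite mask (the purely
spectral truncation contributes ≈1.5%); it concentrates near the
eroded-mask boundary and falls below 2% a further 4 mm inside.  With
SNR 50 noise the round trip lands at ≈13% (the truncated inverse
filter has gain up to 1/tsvd = 20).  These measured classes, not
tighter aspirational ones, are what the regression tests assert.

Unwrapping and background removal operate in radians; the single
radian→ppm conversion (θ/(2π f₀ TE)·10⁶) happens after V-SHARP.

## Dipole inversion

**TKD.**  χ̂ = D⁻¹·Φ̂ with D⁻¹ = 1/D where |D| > δ and sgn(D)/δ
otherwise; sgn(0) := +1 (the ambiguity is a measure-zero set).  Default
δ = 0.25.  For fields whose spectrum vanishes on the clamped region
the inversion is exact to floating point.  For compact sources it is
systematically low: the reconstruction of a point source is scaled by
c(δ) = mean_k min(|D|/δ, 1) (c(0.2) ≈ 0.76, c(0.25) ≈ 0.70,
c(0.4) ≈ 0.52 at 64³) — this attenuation, growing with δ, is exactly
the decrease of ROI means with threshold that motivates comparing δ
values, and the raw estimator reproduces it.
`correct_underestimation=True` divides the map by c(δ); with it the
noiseless end-to-end pipeline recovers nucleus ROI means to ≤12% at
δ = 0.25 and ≤9% at δ = 0.05.  The correction is a single global
factor computed from the kernel, never fit to data.  Note that
trend statistics (slope ratios, correlations, adjusted R²) are
invariant under the global factor, which is why raw TKD is a valid
trend instrument despite the absolute bias.

**L2.**  min ‖F⁻¹DFχ − Φ‖² + λ‖Gχ‖² with G the 3-D forward-difference
gradient.  Both operators are diagonal in k-space, so the exact
minimizer is χ̂ = D·Φ̂/(D² + λE) with E(k) = Σ_a 4 sin²(π f_a h_a)/h_a²
the gradient's squared symbol.  An iterative conjugate-gradient solve
of the explicit normal equations is kept in the test suite as an
independent oracle (agreement < 10⁻⁶ relative).  λ is either given or
chosen as the maximum-curvature corner of the L-curve
(log residual vs log penalty) over a log-spaced sweep of [10⁻⁴, 1];
a curvature profile without an interior positive maximum returns the
mid-range λ with a `degenerate` flag.

**MEDI.**  argmin ‖M∇χ‖₁ + λ‖W(Φ − F⁻¹DFχ)‖₂², where M is 1 where the
magnitude-gradient magnitude is at or below its
(1 − `edge_mask_fraction`) quantile inside the mask (edges are free to
carry χ gradients) and W is the magnitude normalized to unit mean.
Solved by IRLS: each outer iteration minimizes the quadratic majorizer
with weights w = 1/√(|M∇χ_prev|² + ε), ε = 10⁻⁶, via CG warm-started
at the previous iterate — so the smoothed objective is non-increasing
by construction, which the tests assert.  Defaults: λ = 1000 (the mid
value of the comparison grid 800/1000/1500), edge fraction 0.3, 30
outer × 100 CG iterations, relative-change stop at 0.01.
Non-convergence at the caps returns the best iterate flagged
`converged=False`.

**Streaking metric.**  RMS of (χ − truth), demeaned, over a 3-voxel
dilation shell around the true structures — where cone-aligned
artifacts live.  Demeaning makes the metric independent of the
referencing constant.  In the noise-dominated regime the metric
decreases with the TKD threshold, quantifying the artifact-suppression
ordering of larger δ.

## ROI protocol and statistics

Per nucleus, bilateral labels are pooled; the contiguous window of
three axial slices with the largest in-slice ROI area (ties broken
toward the centroid) is selected; mean and population STD (divisor N)
are computed over the ROI voxels inside the reconstruction mask.
Voxels clipped by the eroded mask are excluded and reflected in
`n_voxels`; a nucleus with no surviving voxels is reported
`missing=True` rather than dropped.  Optional tracing jitter replicates
manual re-drawing: each of `n_replicates` replicates randomly erodes
or dilates the ROI by `jitter` voxels and the replicate means are
averaged.  With jitter 0 and one replicate the protocol reduces
exactly to the plain masked mean/STD.

Cohort statistics: Pearson correlation of per-subject ROI means with
age (two-sided p from the t transform, n − 2 df); OLS line with
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2); two-sided paired t-test
between nuclei (sample SD, n − 1 df).  Normality screening uses the
one-sample KS statistic against a normal with sample-estimated
mean/SD; because the parameters are estimated, p-values use the
Lilliefors correction (statsmodels, table method) — the naive KS
p-value would be grossly conservative.  The significance threshold is
0.05 and no multiple-testing correction is applied, matching the
analysis protocol being emulated.

## Problem sizes

Defaults are desk-scale: 48³ for cohort analyses (a 16-subject
noise-free cohort runs in seconds), 64³ for inversion-fidelity and
V-SHARP characterization, 96³ for the uniform-sphere analytic check,
32³ for MEDI property tests, 16³ for the L2 oracle.  The geometry is
specified in mm, so the same anatomy renders at any grid that
contains it.

## Known limitations

* Forward and inverse share the same discrete kernel ("inverse
  crime"); recovery figures exclude model mismatch by design.
* V-SHARP accuracy is boundary-limited (≈5% rel. RMS at the default
  radii); nuclei must sit comfortably inside the eroded mask.
* The TKD underestimation correction assumes compact sources; extended
  sheets or strongly anisotropic structures deviate from c(δ).
* MEDI is exercised at property-test scale; its regularization-path
  behavior at realistic resolution is out of scope.
* Ellipsoidal nuclei and uniform in-nucleus χ are idealizations; no
  claim is made about partial-volume or shape effects on real data.
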