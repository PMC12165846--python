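# Methods

This note documents the models, numerical choices and known limitations of
`ringdecon`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Image formation under rotational symmetry

A linear imaging system maps an object `g(u, v)` to an image

    f(x, y) = ∫∫ g(u, v) h(x, y; u, v) du dv,

where `h(·; u, v)` is the PSF of a point source at `(u, v)`. Most microscopes
are built from rotationally symmetric elements, which constrains the PSF
family: in polar coordinates about the optical centre,

    h̃(ρ, φ; r, θ) = h̃(ρ, φ − θ; r, 0),

i.e. PSFs at the same field radius are rotated copies of one another
(*linear revolution-invariance*, LRI). Substituting this into the
superposition integral collapses it to a radial integral of 1D circular
convolutions over the angle,

    f̃(ρ, φ) = ∫ r (g̃ ∗_θ h̃)(ρ, φ; r, 0) dr,

the *ring convolution* `f = g ⊚ h`. Evaluating the angular convolutions with
1D FFTs gives an `O(N³ log N)` forward model versus `O(N⁴)` for brute-force
superposition, with no isoplanatic-patch or PSF-interpolation heuristics.

### Discretization

* **Polar grid.** `K = ⌈N√2/2⌉ + 1` radii (≈1 px spacing out to the image
  corners) and `M` = smallest multiple of 4 ≥ `⌈2π r_max⌉` angles, so the
  outermost ring is not angularly undersampled. Resampling both ways is
  bilinear; each direction has an exact adjoint (scatter with the same
  weights), which the solvers rely on.
* **Quadrature.** Ring `j` carries the area of its polar cell,
  `w_j = r_j Δr Δθ`, and the centre ring carries the area of its half-pixel
  disc per angular sample, `w_0 = πΔr²/(4M)`. With these weights ring
  convolution is an un-fudged Riemann sum of the superposition integral, so
  flux is preserved up to interpolation error with no ad hoc rescaling.
* **Flat-field normalization.** The output is divided by the identity-chain
  response `from_polar(to_polar(1))`, which cancels exactly the polar
  resampling bias (≈1 everywhere except a droop in the outermost edge
  pixels). It deliberately does *not* divide by the full forward response of
  an all-ones image: that would also cancel the physical dimming at the
  sensor edge (blur leaking off-sensor), which the brute-force oracle
  retains, and the two models would then disagree where they are both
  correct.
* **Kernel bank.** The radial PSF stack is rendered on an extended square
  canvas covering the whole polar disc (side ≈ `N√2`), normalized by *total*
  energy. At `θ = 0` the stack radii extend beyond the sensor, so
  sensor-cropped kernels would lose their main lobes at large radii;
  canvas kernels keep the model exact there. The sensor crop is applied to
  the *output*, which is the physically correct order of operations.
* **Equivalence.** The FFT path and the spatial-domain circular convolutions
  implement the same discrete operator and agree to machine precision (the
  discrete form of the convolution theorem on the angular axis).

## Seidel pupil model

Field-dependent PSFs are generated from the five primary (fourth-order)
Seidel aberration coefficients, in waves, through the classical wavefront
expansion over the unit pupil disc:

    W(ρ, φ; H, θ) = W040 ρ⁴ + W131 H ρ³cos(φ−θ) + W222 H²ρ²cos²(φ−θ)
                  + W220 H²ρ² + W311 H³ρcos(φ−θ)

(sphere, coma, astigmatism, field curvature, distortion), with field height
`H = r / r_max` normalized so the corner of the field of view has `H = 1`.
The PSF is `|F⁻¹{exp(i2πW)}|²` on the disc support. Field rotation enters
exactly through `cos(φ − θ)`; image-domain rotation is only ever used as an
independent test oracle. Sub-pixel placement uses pupil tilt, which is exact
on the padded grid.

**Sampling caveat.** With the pupil disc inscribed in the padded grid (the
default, `pad_factor = 2`), the diffraction core is ~2 px wide — which means
the *intensity* is sampled at twice its Nyquist band. The forward model is
internally consistent (model and oracle share the aliasing), but sampled
PSFs at different sub-pixel positions are then not shift-equivalent.
`OpticalGrid(pupil_fraction=0.5)` shrinks the pupil to half the grid
(~4 px core, alias-free intensity); the symmetry tests and the
deconvolution simulation study use it, mimicking a sensor that samples the
spot at twice the diffraction Nyquist rate. Units are normalized throughout
(pixel pitch 1, no physical NA/wavelength mapping).

## Deconvolution

Ring deconvolution solves

    ĝ = argmin_{g≥0} ‖f − g ⊚ h‖² + λ·TV(g)

with anisotropic (L1-of-forward-differences) total variation, λ = 1e-4 by
default for images normalized to [0, 1], and projection onto nonnegativity
each step. The fidelity gradient uses the exact adjoint of the discrete ring
convolution, verified by inner-product tests to float round-off.

The optimizer is adaptive-moment gradient descent with one deliberate
modification: the second-moment accumulator is a *scalar* (the mean squared
gradient) rather than per-component. Per-component normalization turns the
vanishing gradients of null-space components — frequencies the PSF does not
pass — into full-size random steps and fills the estimate with noise; the
scalar variant preserves the gradient direction, so with λ = 0 on noiseless
band-limited data the iterative solution matches the closed-form Wiener
filter. The step decays quadratically to ~1% of its initial value
(default 0.1) over the run (default 300 iterations), which settles the
iterations into a monotone tail; stopping requires five consecutive
relative changes below `tol`.

LSI baselines share all conventions: Wiener filtering (closed-form frequency
filter with a noise-to-signal floor), Richardson–Lucy (multiplicative,
flux-preserving; cross-checked against scikit-image), and iterative least
squares with a single PSF. PSFs stored as even-sided images have their
centre on a half-integer pixel; all LSI operations build the OTF with an
exact sub-pixel phase ramp rather than integer shifts.

## Single-image Seidel calibration

The five coefficients are fitted to one image of randomly scattered point
sources by matching a joint model image — a sum of pupil-model PSFs with
per-source amplitudes and a shared background, both solved in closed form
every iteration — over the union of windows (default 31 px) around the
sources. Joint amplitudes also account for overlapping flare tails between
neighbours. The gradient is analytic through the pupil FFT (two batched FFTs
per iteration regardless of the number of coefficients), exact to ~1e-9
against finite differences.

The problem is nonconvex with a characteristic failure mode: wrap-around
local minima displaced by about one wave in the spherical (and sometimes
coma) term. The search therefore combines multi-start Adam (zeros plus
seeded random starts), projection into the 0–3 wave range of practical
systems (which also removes the sphere sign ambiguity of intensity-only
pupil fitting), and a coarse 1D sweep of the sphere and coma axes around the
best solution with re-polish. Runs that reach a numerically zero residual
stop early. Not every trial converges to the global minimum — the
acceptance study measures the median and the fraction of converged trials.

**Source positions and distortion.** The model places each PSF's unaberrated
image point at the position carried by the source record. When those records
are the generated ground-truth positions (the simulation protocol), the
model is exact at the true coefficients and distortion is identified by the
tilt shift of the pattern relative to the record. When positions come from
peak detection on a real image, the distortion shift is already absorbed
into the detected positions and is fundamentally inseparable from them; for
that use `freeze_distortion=True`, which mirrors how such systems are
calibrated in practice (distortion then reads as zero).

**Noise.** Least squares is the maximum-likelihood estimator under additive
Gaussian noise, so there is no further estimator headroom at fixed data. At
−20 dB SNR (noise variance 100× the mean signal power of the frame) the
fitted-PSF error of a fit initialized *at the truth* is already ≈20%
relative L2 on this protocol — the tolerance of the acceptance check sits at
the information limit, and the from-scratch search lands somewhat above it.
Matched-filter smoothing and multiscale initialization were evaluated and
rejected: both discard the informative high-frequency structure and degrade
the estimator. The weaker denoising property — PSFs regenerated from a noisy
fit are far closer to the clean truth than the raw noisy data — holds with a
wide margin and is what the method is used for in practice.

The optical centre is estimated from the peak of the image's
autoconvolution (correlation with the 180°-rotated copy), refined by a
parabolic fit, with the geometric centre as fallback for flat landscapes.

## Blind spherical search

Given only a blurry image, the spherical coefficient is searched by
maximizing the total absolute image gradient of the deconvolved image
(Richardson–Lucy inner step, 20 iterations), with finite-difference
gradients and adaptive-moment updates clamped to 0–3 waves. A property of
this surrogate, measured across phantom families, inner solvers (TV least
squares, Wiener over a range of floors, RL at several iteration counts) and
metric normalizations: it is monotone in deblurring strength, so its
maximum sits a few tenths of a wave *past* the true coefficient —
over-deconvolution steepens edges faster than mismatch artifacts destroy
them. The recovered coefficient therefore tracks the truth monotonically
with a positive bias of roughly +0.3 to +0.5 waves, and the deconvolved
output is reliably sharper than the input. Users who need unbiased
coefficients should calibrate with a bead image instead.

## Light-sheet (lateral symmetry) extension

In light-sheet microscopy the detection optics are space-invariant but the
Gaussian illumination sheet focuses along one lateral axis `u`:

    h(x,y,z; u,v,t) = h_p(x−u, y−v, z−t) · N(z−t; σ(u)),
    σ(u) = α √(1 + (βu)²),

with the printed `1/(σ√2π)` normalization kept — the sheet truncation
physically removes flux, so kernels are *not* re-normalized per `u` (total
flux decreases away from the waist once the sheet outgrows the kernel
support). `α` is the axial spread at the waist (voxels), `β` the spread
growth rate (1/voxel). The base imaging PSF `h_p` is a scalar-diffraction
defocus model (pupil disc of relative cutoff `na` with `defocus_rate` waves
of defocus per voxel of z), and a measured 3D array can be injected in its
place. Sheet convolution sums 2D (v, t)-plane convolutions over `u`
(`O(N⁴ log N)`); boundaries are periodic on all three axes, a declared
choice that makes the `β = 0` limit coincide exactly with circular 3D FFT
convolution and gives an exact adjoint. Kernels are indexed by the
object-space `u` of the input slice, with the waist at the centre of the
first axis. Sheet deconvolution reuses the TV least-squares solver
unchanged. `(α, β)` are fitted to detected beads in a calibration stack by
bounded quasi-Newton least squares with closed-form per-bead amplitudes;
measured PSF sets can instead be interpolated (convex combination of the
two bracketing `u` positions, clamped at the ends).

## Synthetic data

All fixtures are generated in-process, seeded, and pure functions of their
spec. Test objects are procedural mixtures of filaments, discs and point
scatterers with a cosine border taper (no downloaded datasets). Calibration
sources are uniform over the sensor square minus a margin — the spec'd
"field-of-view disc" of radius `r_max` lies mostly outside the sensor — with
rejection-sampled minimum separation and amplitudes uniform in [0.5, 1] to
exercise the amplitude nuisances. SNR is defined as
`10·log10(mean signal power / noise variance)` over the full frame; this is
stated explicitly because "−20 dB" is otherwise ambiguous for sparse images.
Coefficient samplers cover 0–3 waves, i.i.d. uniform or a shuffled
per-coefficient grid jittered by 10% of the grid spacing.

What the generators do *not* emulate: detector quantization and read-out
structure, background autofluorescence, optical vignetting beyond the
sensor crop, sample-induced aberrations, and any field dependence beyond
the five primary Seidel terms. Passing tests demonstrate internal
consistency of the models and solvers under these idealized conditions, not
performance on a particular instrument.

## Problem sizes and defaults

The simulation studies run at 64×64 (forward model, calibration,
deconvolution; 10 sources per calibration image, 50 recovery trials with
2-start/120-iteration fits), 32³-to-48×32×24 volumes for the light-sheet
studies, and 16–256 px for the runtime scaling measurements. These sizes
make every headline behaviour measurable at interactive runtimes; the
operators themselves are size-generic, and ring deconvolution switches to a
single-precision kernel cache (with an optional numba-compiled gather) for
large stacks where the computation is memory-bandwidth bound.

## Known limitations

* The polar transforms are bilinear; forward-model accuracy is ~1% relative
  L2 and edge pixels beyond the last ring droop (cancelled by the
  flat-field map). Reconstructions inherit an amplified version of this
  discretization error, so reconstructions from two *different* discrete
  forward models of the same system (ring vs LSI in the zero-off-axis
  limit) agree only to ~10%, not to the forward-level ~1–3%.
* Distortion is unidentifiable from detection-estimated positions (see
  above); fit it only under the simulation protocol or freeze it.
* The blind search inherits the sharpness surrogate's positive bias.
* No vectorial/high-NA pupil model, apodization, chromatic terms, or
  higher-order Seidel coefficients.
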