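# ringdecon

Spatially varying deblurring for rotationally symmetric microscopes.

Standard deconvolution assumes the point spread function (PSF) is the same
everywhere in the field of view. Real systems — miniature microscopes,
high-NA objectives, fiber endoscopes — violate this badly away from the
optical axis, which is exactly where deconvolution then fails. Fully
spatially varying deblurring is rigorous but needs one PSF per pixel and
`O(N⁴)` compute.

`ringdecon` exploits the middle ground: for a system that is symmetric about
its optical axis, PSFs at the same field radius are rotated copies of one
another. Under that symmetry the superposition integral collapses to a
radial stack of 1D circular convolutions over the angle — *ring
convolution*,

    f̃(ρ, φ) = Σ_j w_j · F⁻¹_θ{ F_θ{g̃(·, j)} · F_θ{h̃⁽ʲ⁾(·, ρ)} }(φ),

an **exact** forward model for such systems that runs in `O(N³ log N)`.
Deblurring ("ring deconvolution") is TV-regularized least squares,

    ĝ = argmin_{g≥0} ‖f − g ⊚ h‖² + λ·TV(g),

solved with adaptive-moment gradient descent and the exact adjoint of the
discrete forward model. The whole radially varying PSF family is calibrated
from a **single image of scattered beads** by fitting the five primary
Seidel aberration coefficients (sphere, coma, astigmatism, field curvature,
distortion, in waves) through a differentiable pupil model. The same idea
applied to *lateral* symmetry gives sheet convolution/deconvolution for
light-sheet microscopy, where the Gaussian illumination sheet makes the PSF
grow axially away from the beam waist, `σ(u) = α√(1+(βu)²)`.

The package is a library first (`import ringdecon`), with short narrative
scripts in `examples/` and a thin `rdm` command line for the common
pipelines.

## Worked example

```python
import numpy as np
from ringdecon import (OpticalGrid, SeidelCoefficients, RingOperator,
                       render_radial_psf_stack, true_blur, ring_deconvolve,
                       standard_deconvolve, render_psf, fit_seidel,
                       make_calibration_image, make_phantom, psnr,
                       SolverConfig)

grid = OpticalGrid(n=64, pupil_fraction=0.5)   # well-sampled 64x64 sensor
truth = SeidelCoefficients(sphere=0.3, coma=1.2, astigmatism=1.0,
                           field_curvature=1.0, distortion=0.2)

# single-image calibration from 10 scattered beads
cal, _ = make_calibration_image(truth, 10, grid, seed=7)
fit = fit_seidel(cal, grid, SolverConfig(seed=0))
print(np.round(fit.coefficients.as_array(), 3))
# [0.301 1.204 0.993 0.995 0.18 ]

# blur a phantom with the brute-force spatially varying oracle, then deblur
g = make_phantom(64, seed=50)
f = np.clip(true_blur(g, truth, grid), 0, None)
op = RingOperator(render_radial_psf_stack(fit.coefficients, grid, 47))
ring = ring_deconvolve(f, op).estimate
std = standard_deconvolve(f, render_psf(fit.coefficients, 0, 0, grid)).estimate
print(f"PSNR blurred {psnr(f, g):.1f} dB | standard {psnr(std, g):.1f} dB "
      f"| ring {psnr(ring, g):.1f} dB")
# PSNR blurred 20.8 dB | standard 22.9 dB | ring 29.8 dB
```

The calibration recovers the five aberration weights from one bead image;
ring deconvolution then outperforms single-PSF deconvolution everywhere, and
by the largest margin near the corners of the field of view where the PSF
deviates most from the centre PSF. (Numbers above are from this exact
script; seeds make them reproducible.)

More walkthroughs in `examples/`: forward-model accuracy against the
brute-force oracle, single-image calibration, ring vs standard
deconvolution, light-sheet sheet deconvolution, and blind spherical search.

## Command line

```sh
rdm simulate beads --coeffs c.json -n 64 -j 10 -o beads.tif
rdm calibrate beads.tif -o fit.json --freeze-distortion
rdm deblur image.tif --method ring --coeffs fit.json -o deblurred.tif
rdm sheet calibrate stack.tif -o model.json
rdm sheet deblur stack.tif --model model.json -o out.tif
```

Every run writes a JSON provenance record (tool version, config hash, seed)
next to its output.

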