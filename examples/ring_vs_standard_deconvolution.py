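"""Ring deconvolution vs single-PSF deconvolution on a true-blurred image.

Blurs a phantom with the brute-force spatially varying model, deblurs it
with (a) ring deconvolution and (b) standard TV least squares using only the
centre PSF, and prints PSNR globally and in the outer quarter of the field
of view, where the space-invariance assumption is worst.
"""

import numpy as np

from ringdecon import (OpticalGrid, RingOperator, SeidelCoefficients,
                       SolverConfig, make_phantom, psnr, render_psf,
                       render_radial_psf_stack, ring_deconvolve,
                       standard_deconvolve, true_blur)

grid = OpticalGrid(n=64, pupil_fraction=0.5)  # sensor sampled at 2x Nyquist
coeffs = SeidelCoefficients(0.3, 1.4, 1.0, 1.0, 0.2)
g = make_phantom(64, seed=52)
f = np.clip(true_blur(g, coeffs, grid), 0, None)

op = RingOperator(render_radial_psf_stack(coeffs, grid, 47))
ring = ring_deconvolve(f, op, SolverConfig(max_iters=300)).estimate
std = standard_deconvolve(f, render_psf(coeffs, 0.0, 0.0, grid),
                          "iterative_ls", SolverConfig(max_iters=300)).estimate

yy, xx = np.mgrid[:64, :64]
outer = np.hypot(yy - 31.5, xx - 31.5) >= 0.75 * grid.r_max


def psnr_outer(est):
    return 10 * np.log10(g.max() ** 2 / np.mean((est[outer] - g[outer]) ** 2))


print(f"global PSNR : blurred {psnr(f, g):.1f} dB | standard "
      f"{psnr(std, g):.1f} dB | ring {psnr(ring, g):.1f} dB")
print(f"outer 25%   : standard {psnr_outer(std):.1f} dB | ring "
      f"{psnr_outer(ring):.1f} dB")
print("\nBoth methods see the same data; ring deconvolution additionally "
      "knows how the PSF rotates and spreads with field radius, which pays "
      "off most in the corners.")
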