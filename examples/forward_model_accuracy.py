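"""Ring convolution vs the brute-force spatially varying oracle.

Blurs one procedural phantom with three forward models — brute-force
per-pixel PSF superposition ("true blur"), ring convolution, and standard
(space-invariant) convolution with the centre PSF — at a mild and a severe
aberration level, and prints the relative mean-squared error of the two fast
models against the oracle.
"""

import numpy as np

from ringdecon import (OpticalGrid, RingOperator, SeidelCoefficients,
                       lsi_convolve, make_phantom, rel_mse, render_psf,
                       render_radial_psf_stack, true_blur)

grid = OpticalGrid(n=64)
g = make_phantom(64, seed=3)

for label, coeffs in [
    ("mild (0.3 waves off-axis)", SeidelCoefficients(0.2, 0.3, 0.2, 0.2, 0.1)),
    ("severe (2 waves off-axis)", SeidelCoefficients(0.5, 2.0, 1.5, 1.5, 0.5)),
]:
    f_true = true_blur(g, coeffs, grid)          # O(N^4) oracle
    stack = render_radial_psf_stack(coeffs, grid, 47)
    f_ring = RingOperator(stack).apply(g)        # O(N^3 log N)
    f_lsi = lsi_convolve(g, render_psf(coeffs, 0.0, 0.0, grid))
    print(f"{label}:")
    print(f"  ring convolution vs oracle: rel MSE {rel_mse(f_ring, f_true):.5f}")
    print(f"  standard convolution:       rel MSE {rel_mse(f_lsi, f_true):.5f}")

print("\nRing convolution stays at the interpolation floor regardless of the "
      "aberration strength; the space-invariant model degrades with it "
      "because the edge PSFs stop resembling the centre PSF.")
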