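"""Sheet deconvolution of a synthetic light-sheet bead volume.

The illumination sheet focuses along the first volume axis: the PSF's axial
(z) extent grows away from the beam waist as sigma(u) = alpha*sqrt(1+(beta*u)^2).
This script fits (alpha, beta) from a bead calibration volume, blurs a bead
sample, deblurs it with sheet deconvolution and with standard 3D
deconvolution (waist PSF everywhere), and prints the axial FWHM statistics
across the field of view.
"""

import numpy as np

from ringdecon import (LSFMPSFModel, SheetOperator, SolverConfig,
                       fit_lsfm_model, make_bead_volume, measure_fwhm,
                       sheet_deconvolve)

true_model = LSFMPSFModel(alpha=1.5, beta=0.10, kernel_shape=(11, 11, 13))

# calibration: fit (alpha, beta) from a separate bead stack
cal_stack, _ = make_bead_volume(true_model, 8, (48, 32, 24), seed=21)
fit = fit_lsfm_model(cal_stack, LSFMPSFModel(alpha=1.0, beta=0.2,
                                             kernel_shape=(11, 11, 13)))
print(f"fitted alpha {fit.alpha:.3f} (true 1.5), beta {fit.beta:.4f} (true 0.10)")

# sample: blur, then deblur both ways
truth, pos = make_bead_volume(true_model, 8, (48, 32, 24), seed=9)
g = truth / truth.max()
op = SheetOperator(g.shape, fit)
f = op.apply(g)
cfg = SolverConfig(max_iters=150)
est_sheet = sheet_deconvolve(f, op, cfg).estimate
op_std = SheetOperator(g.shape, LSFMPSFModel(alpha=fit.alpha, beta=0.0,
                                             kernel_shape=(11, 11, 13)))
est_std = sheet_deconvolve(f, op_std, cfg).estimate


def axial_fwhms(vol):
    vals = []
    for p in pos:
        try:
            vals.append(measure_fwhm(vol, p, axis=2))
        except ValueError:
            pass
    return np.array(vals)


for name, est in [("sheet deconvolution", est_sheet),
                  ("standard 3D deconvolution", est_std)]:
    fw = axial_fwhms(est)
    print(f"{name}: axial FWHM {fw.mean():.2f} +/- {fw.std():.2f} voxels")
print("\nSheet deconvolution knows the sheet thickens away from the waist, "
      "so beads far from the centre are restored as sharply as central ones "
      "— smaller mean and spread of the axial width.")
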