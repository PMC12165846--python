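"""FFT helpers for space-invariant (LSI) convolution with sub-pixel centring.

A PSF stored as an even-sided image has its optical centre on a half-integer
pixel (e.g. (31.5, 31.5) for 64 x 64), which integer-shift convolution cannot
represent.  These helpers build the optical transfer function with an exact
sub-pixel phase ramp so LSI convolution, correlation and the closed-form
inverse filters all agree with the spatially varying oracle's placement
convention.  Boundaries are circular.
"""

from __future__ import annotations

import numpy as np

__all__ = ["psf_otf", "lsi_convolve", "lsi_correlate"]


def psf_otf(psf: np.ndarray, center: tuple[float, float] | None = None) -> np.ndarray:
    """Optical transfer function of a PSF image with its centre moved to the origin.

    ``center`` defaults to the geometric centre ``((n-1)/2, (n-1)/2)``.
    """
    psf = np.asarray(psf, dtype=float)
    n0, n1 = psf.shape
    if center is None:
        center = ((n0 - 1) / 2.0, (n1 - 1) / 2.0)
    otf = np.fft.fft2(psf)
    fy = np.fft.fftfreq(n0)[:, None]
    fx = np.fft.fftfreq(n1)[None, :]
    return otf * np.exp(2j * np.pi * (fy * center[0] + fx * center[1]))


def lsi_convolve(image: np.ndarray, psf: np.ndarray,
                 center: tuple[float, float] | None = None) -> np.ndarray:
    """Circular convolution with a PSF centred at ``center`` (sub-pixel exact)."""
    otf = psf_otf(psf, center)
    return np.fft.ifft2(np.fft.fft2(np.asarray(image, dtype=float)) * otf).real


def lsi_correlate(image: np.ndarray, psf: np.ndarray,
                  center: tuple[float, float] | None = None) -> np.ndarray:
    """Adjoint of :func:`lsi_convolve` (correlation with the flipped PSF)."""
    otf = psf_otf(psf, center)
    return np.fft.ifft2(np.fft.fft2(np.asarray(image, dtype=float)) * np.conj(otf)).real
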