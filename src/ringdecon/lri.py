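"""The linear revolution-invariant (LRI) forward model: ring convolution.

For a rotationally symmetric system the PSF at polar source position
``(r, theta)`` is the ``theta``-rotation of the PSF at ``(r, 0)``.  Under that
symmetry the superposition integral collapses to a radial integral of 1D
circular convolutions over the angular coordinate:

    f~(rho, phi) = sum_j  w_j * (g~(:, j) (*) h~^(j)(:, rho))(phi)

where ``(*)`` is circular convolution over the angle axis, ``g~``/``h~`` are
polar resamplings and ``w_j = r_j * dr * dtheta`` is the area of a polar
quadrature cell (the centre ring uses the area of its half-pixel disc).  The
angular convolutions are evaluated with 1D FFTs, giving ``O(N^3 log N)``
runtime against ``O(N^4)`` for brute-force superposition.

This module provides the FFT path (:func:`ring_convolve`), a spatial-domain
equivalence oracle (:func:`ring_convolve_direct`), the brute-force spatially
varying oracle (:func:`true_blur`) and the exact adjoint
(:func:`ring_correlate`) needed by the iterative solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .polar import (
    PolarGridSpec,
    PolarImage,
    from_polar,
    from_polar_adjoint,
    to_polar,
    to_polar_adjoint,
)
from .seidel import OpticalGrid, SeidelCoefficients, _PupilBasis, _crop, \
    _fields_to_psfs, _tilt_for_shift, canvas_side

__all__ = [
    "RadialPSFStack",
    "RingOperator",
    "ring_convolve",
    "ring_convolve_direct",
    "ring_correlate",
    "true_blur",
    "ideal_impulse_stack",
]

# per-j angular spectra are cached in double precision while modest, in
# single precision for large problems (percent-level accuracy is ample there),
# and recomputed on the fly beyond that
_CACHE_SPECTRUM_MAX_ELEMS = 12_000_000
_CACHE_SPECTRUM_MAX_ELEMS_F32 = 80_000_000


@dataclass
class RadialPSFStack:
    """Kernel bank for ring convolution: PSFs along one radial line.

    ``psfs[j]`` is the full-disc canvas image of a point source at polar
    position ``(radii[j], theta=0)`` about the canvas centre (see
    :func:`ringdecon.seidel.render_canvas_psf`).
    """

    psfs: np.ndarray
    radii: np.ndarray
    grid: OpticalGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.psfs = np.asarray(self.psfs, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.psfs.ndim != 3 or self.psfs.shape[1] != self.psfs.shape[2]:
            raise ValueError(f"psfs must be (K, C, C), got {self.psfs.shape}")
        if len(self.psfs) != len(self.radii):
            raise ValueError("number of PSFs and radii differ")
        if len(self.radii) >= 2 and not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.psfs < -1e-12):
            raise ValueError("PSFs must be nonnegative")

    @property
    def num_radii(self) -> int:
        return len(self.radii)

    @property
    def canvas(self) -> int:
        return self.psfs.shape[1]


try:
    from numba import njit as _njit

    @_njit(fastmath=True, cache=True)
    def _gather_stack_jit(images, idx, w):  # pragma: no cover - compiled
        k = images.shape[0]
        p = idx.shape[1]
        out = np.zeros((k, p), dtype=np.float32)
        for j in range(k):
            img = images[j]
            for t in range(p):
                acc = 0.0
                for c in range(4):
                    acc += w[c, t] * img[idx[c, t]]
                out[j, t] = acc
        return out
except ImportError:  # pragma: no cover
    _gather_stack_jit = None


def _to_polar_batch(images: np.ndarray, spec: PolarGridSpec,
                    transpose: bool = False, dtype=float) -> np.ndarray:
    """Polar-transform a stack of same-shape images, sharing the bilinear
    weights across the stack (the per-image path recomputes them).

    ``transpose`` returns (stack, radius, angle) instead of
    (stack, angle, radius), which puts the angular axis contiguous for the
    1D FFTs.  The single-precision tier uses a fused compiled gather when
    numba is available (the access pattern is memory-latency bound).
    """
    from .polar import _bilinear_weights, _polar_sample_coords

    images = np.asarray(images, dtype=dtype)
    rows, cols = _polar_sample_coords(spec)
    if transpose:
        rows, cols = rows.T.copy(), cols.T.copy()
    terms = list(_bilinear_weights(rows, cols, images.shape[1:]))
    if dtype == np.float32 and _gather_stack_jit is not None:
        side = images.shape[2]
        idx = np.stack([(rr * side + cc).ravel() for rr, cc, _ in terms])
        w = np.stack([w_.ravel() for _, _, w_ in terms]).astype(np.float32)
        flat = np.ascontiguousarray(images.reshape(len(images), -1))
        return _gather_stack_jit(flat, idx, w).reshape(
            (len(images),) + rows.shape)
    out = np.zeros((len(images),) + rows.shape, dtype=dtype)
    for rr, cc, w in terms:
        out += w[None].astype(dtype) * images[:, rr, cc]
    return out


def _default_spec_for_stack(stack: RadialPSFStack) -> PolarGridSpec:
    r_max = float(stack.radii[-1])
    m = 4 * math.ceil(math.ceil(2 * np.pi * r_max) / 4)
    c0 = (stack.canvas - 1) / 2.0
    return PolarGridSpec(num_angles=m, num_radii=stack.num_radii,
                         center=(c0, c0), max_radius=r_max)


class RingOperator:
    """Precomputed linear operator for ring convolution and its adjoint.

    Building the operator polar-transforms every stack kernel once; repeated
    applies (as in iterative deconvolution) then cost one 2D resample and a
    batch of 1D FFTs each.
    """

    def __init__(self, stack: RadialPSFStack, spec: PolarGridSpec | None = None,
                 flat_field: bool = True):
        self.stack = stack
        self.n = stack.grid.n
        if spec is None:
            spec = _default_spec_for_stack(stack)
        # the image-side polar grid shares (M, K, r_max) with the canvas grid
        # but is centred on the sensor
        self.h_spec = spec
        self.g_spec = PolarGridSpec(
            num_angles=spec.num_angles, num_radii=spec.num_radii,
            center=stack.grid.center, max_radius=spec.max_radius)
        m, k = spec.num_angles, spec.num_radii

        self._single = stack.num_radii**2 * spec.num_angles > _CACHE_SPECTRUM_MAX_ELEMS
        dtype = np.float32 if self._single else float
        radii = self.g_spec.radii
        if not np.allclose(radii, stack.radii, atol=1e-9 * max(1.0, radii[-1])):
            h_t = np.moveaxis(self._polar_stack_resampled(radii), 1, 2)
            h_t = np.ascontiguousarray(h_t.astype(dtype))
        else:
            h_t = _to_polar_batch(stack.psfs, self.h_spec, transpose=True,
                                  dtype=dtype)

        dr = self.g_spec.dr
        dtheta = self.g_spec.dtheta
        w = radii * dr * dtheta
        w[0] = np.pi * dr**2 / (4.0 * m)  # area of the half-pixel centre disc / M
        self.weights = w

        # spectra are stored as (K_j, K_i, M) so the angular FFT runs over a
        # contiguous axis; large problems use single precision end to end
        # (memory-bandwidth bound; percent-level accuracy is ample there)
        self._h_hat = np.fft.fft(h_t, axis=-1)

        if flat_field:
            ones = np.ones((self.n, self.n))
            ff = from_polar(to_polar(ones, self.g_spec), self.n)
            self.flat = np.clip(ff, 1e-3, None)
        else:
            self.flat = None

    def _polar_stack_resampled(self, radii: np.ndarray) -> np.ndarray:
        """Linear interpolation of polar-transformed kernels along the radius index."""
        base = _to_polar_batch(self.stack.psfs, self.h_spec)
        k = len(radii)
        out = np.empty((k, base.shape[1], base.shape[2]))
        for i, r in enumerate(radii):
            j = np.searchsorted(self.stack.radii, r, side="right") - 1
            j = min(max(j, 0), len(self.stack.radii) - 2)
            r0, r1 = self.stack.radii[j], self.stack.radii[j + 1]
            t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
            out[i] = (1 - t) * base[j] + t * base[j + 1]
        return out

    def apply(self, g: np.ndarray) -> np.ndarray:
        """Ring convolution of an ``n x n`` image."""
        g = np.asarray(g, dtype=float)
        if g.shape != (self.n, self.n):
            raise ValueError(f"expected image of shape {(self.n, self.n)}, got {g.shape}")
        g_pol = to_polar(g, self.g_spec).values
        g_hat = np.fft.fft(g_pol, axis=0)                    # (M, K)
        if self._single:
            g_hat = g_hat.astype(np.complex64)
        f_hat = np.einsum("j,mj,jim->mi",
                          self.weights.astype(g_hat.real.dtype), g_hat,
                          self._h_hat, optimize=True)
        f_pol = np.fft.ifft(f_hat, axis=0).real
        out = from_polar(PolarImage(f_pol, self.g_spec), self.n)
        if self.flat is not None:
            out = out / self.flat
        return out

    def adjoint(self, f: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`apply` (ring correlation)."""
        f = np.asarray(f, dtype=float)
        if f.shape != (self.n, self.n):
            raise ValueError(f"expected image of shape {(self.n, self.n)}, got {f.shape}")
        if self.flat is not None:
            f = f / self.flat
        f_pol = from_polar_adjoint(f, self.g_spec).values
        f_hat = np.fft.fft(f_pol, axis=0)
        if self._single:
            f_hat = f_hat.astype(np.complex64)
        g_hat = np.einsum("j,mi,jim->mj",
                          self.weights.astype(f_hat.real.dtype), f_hat,
                          np.conj(self._h_hat), optimize=True)
        g_pol = np.fft.ifft(g_hat, axis=0).real
        return to_polar_adjoint(PolarImage(g_pol, self.g_spec), self.n)


def ring_convolve(g: np.ndarray, stack: RadialPSFStack,
                  spec: PolarGridSpec | None = None,
                  flat_field: bool = True) -> np.ndarray:
    """Blur an image with the LRI forward model (FFT path, Algorithm form)."""
    return RingOperator(stack, spec=spec, flat_field=flat_field).apply(g)


def ring_correlate(f: np.ndarray, stack: RadialPSFStack,
                   spec: PolarGridSpec | None = None,
                   flat_field: bool = True) -> np.ndarray:
    """Adjoint of :func:`ring_convolve`: <A g, f> == <g, A^T f> exactly."""
    return RingOperator(stack, spec=spec, flat_field=flat_field).adjoint(f)


def ring_convolve_direct(g: np.ndarray, stack: RadialPSFStack,
                         spec: PolarGridSpec | None = None,
                         flat_field: bool = True) -> np.ndarray:
    """Spatial-domain ring convolution (no angular FFTs).

    Identical discretization to :func:`ring_convolve`; the two agree to
    floating-point round-off, which is the discrete statement of the ring
    convolution theorem.  Quadratic in the angle count, so intended as an
    equivalence oracle on small images.
    """
    op = RingOperator(stack, spec=spec, flat_field=flat_field)
    g = np.asarray(g, dtype=float)
    g_pol = to_polar(g, op.g_spec).values
    m = op.g_spec.num_angles
    h_pol = np.moveaxis(np.fft.ifft(op._h_hat, axis=-1).real, 2, 1)
    # circulant index: out[t] = sum_m a[m] * b[(t - m) mod M]
    t_idx = (np.arange(m)[:, None] - np.arange(m)[None, :]) % m
    f_pol = np.zeros_like(g_pol)
    for j, w in enumerate(op.weights):
        circ = h_pol[j][t_idx]               # (M_t, M_m, K_i)
        f_pol += w * np.einsum("m,tmi->ti", g_pol[:, j], circ)
    out = from_polar(PolarImage(f_pol, op.g_spec), op.n)
    if op.flat is not None:
        out = out / op.flat
    return out


def ideal_impulse_stack(grid: OpticalGrid, num_radii: int) -> RadialPSFStack:
    """Identity-optics stack: a sub-pixel unit impulse at each ``(r_j, 0)``.

    With these kernels ring convolution reduces to the polar round trip, so
    the output matches the input to interpolation tolerance.
    """
    radii = np.linspace(0.0, grid.r_max, num_radii)
    c = canvas_side(grid)
    c0 = (c - 1) / 2.0
    psfs = np.zeros((num_radii, c, c))
    for j, r in enumerate(radii):
        row, col = c0, c0 + r
        i0, j0 = int(np.floor(row)), int(np.floor(col))
        fr, fc = row - i0, col - j0
        for di, dj, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            if 0 <= i0 + di < c and 0 <= j0 + dj < c and w > 0:
                psfs[j, i0 + di, j0 + dj] = w
    return RadialPSFStack(psfs=psfs, radii=radii, grid=grid)


def true_blur(g: np.ndarray, coeffs: SeidelCoefficients, grid: OpticalGrid,
              chunk: int = 96) -> np.ndarray:
    """Brute-force spatially varying blur: superimpose one PSF per pixel.

    The discrete superposition integral, ``O(N^4 log N)``; this is the
    ground-truth oracle that ring convolution is checked against.  Each
    pixel's full-canvas PSF is accumulated and the sum is cropped to the
    sensor afterwards, so edge vignetting is physical.
    """
    g = np.asarray(g, dtype=float)
    n = grid.n
    if g.shape != (n, n):
        raise ValueError(f"expected image of shape {(n, n)}, got {g.shape}")
    c = canvas_side(grid)
    l = 2 * c
    basis = _PupilBasis.get(l, grid.pupil_fraction)
    cy, cx = grid.center
    rows, cols = np.nonzero(g)
    amps = g[rows, cols]

    dy = rows - cy
    dx = cols - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    h = r / grid.r_max

    q_ct = basis.xhat
    q_st = basis.yhat
    buf = np.zeros((c, c))
    start = (c + 1) // 2
    # sub-pixel offset between the canvas centre and the natural FFT centre
    sub = (c - 1) / 2.0 - (l // 2 - start)
    for lo in range(0, len(rows), chunk):
        sl = slice(lo, lo + chunk)
        ct = np.cos(theta[sl])[:, None, None]
        st = np.sin(theta[sl])[:, None, None]
        hh = h[sl][:, None, None]
        q = q_ct[None] * ct + q_st[None] * st
        w = (coeffs.sphere * basis.rho4[None]
             + coeffs.coma * hh * basis.rho2[None] * q
             + coeffs.astigmatism * hh**2 * q * q
             + coeffs.field_curvature * hh**2 * basis.rho2[None]
             + coeffs.distortion * hh**3 * q)
        ty, tx = _tilt_for_shift(dy[sl] + sub, dx[sl] + sub)
        w += (basis.fraction * tx)[:, None, None] * basis.xhat[None] \
            + (basis.fraction * ty)[:, None, None] * basis.yhat[None]
        psfs = _crop(_fields_to_psfs(w, basis), c, start)
        buf += np.tensordot(amps[sl], psfs, axes=(0, 0))
    off = (c - n) // 2
    return buf[off:off + n, off:off + n]
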