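"""Sheet convolution and deconvolution for light-sheet fluorescence microscopy.

In LSFM the detection optics are space-invariant but the Gaussian illumination
sheet focuses along one lateral axis ``u``: the PSF's axial (z) extent grows
away from the beam waist while nothing varies along the other two axes.  The
forward model then collapses to an integral over ``u`` of 2D convolutions in
the invariant (v, t) plane:

    f(x, y, z) = sum_u ( g(u, :, :) conv_{v,t} h(. ; u) )(x, y, z)

which costs ``O(N^4 log N)`` instead of the general ``O(N^6)``.

The spatially varying PSF is either interpolated from a measured bead stack
(:func:`interpolate_psf`) or generated from a two-parameter Gaussian-beam
model on top of a space-invariant imaging PSF ``h_p``:

    h(x,y,z; u,v,t) = h_p(x-u, y-v, z-t) * N(z-t; sigma(u)),
    sigma(u) = alpha * sqrt(1 + (beta*u)^2)

with the 1/(sigma*sqrt(2*pi)) normalization kept — sheet truncation really
does remove flux, so PSFs are *not* re-normalized per ``u``.  ``h_p`` here is
a scalar-diffraction defocus model (pupil disc with a defocus phase), and a
user-measured 3D array can be injected in its place.

Discrete boundaries are periodic on all three axes, so the ``beta = 0`` limit
coincides exactly with circular 3D FFT convolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.ndimage import maximum_filter

from .deblur import DeblurResult, SolverConfig, iterative_least_squares

__all__ = [
    "LSFMPSFModel",
    "AxialPSFSet",
    "sigma_profile",
    "base_imaging_psf",
    "lsfm_psf",
    "interpolate_psf",
    "SheetOperator",
    "sheet_convolve",
    "sheet_correlate",
    "sheet_blur_direct",
    "sheet_deconvolve",
    "detect_beads",
    "fit_lsfm_model",
    "measure_fwhm",
]


@dataclass(frozen=True)
class LSFMPSFModel:
    """Gaussian-beam light-sheet PSF model.

    ``alpha`` is the axial spread (voxels) at the waist, ``beta`` the spread
    growth rate (1/voxel) along the focus axis.  ``na`` (pupil cutoff as a
    fraction of the inscribed disc) and ``defocus_rate`` (waves of defocus per
    voxel of z) parameterize the space-invariant imaging PSF; alternatively a
    measured ``base_psf`` array can be supplied.
    """

    alpha: float
    beta: float
    kernel_shape: tuple[int, int, int] = (17, 17, 17)
    na: float = 0.8
    defocus_rate: float = 0.08
    base_psf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class AxialPSFSet:
    """Measured (or rendered) 3D PSFs indexed by the focus-axis coordinate."""

    psfs: list[np.ndarray]
    u_positions: np.ndarray

    def __post_init__(self) -> None:
        self.u_positions = np.asarray(self.u_positions, dtype=float)
        if len(self.psfs) == 0:
            raise ValueError("empty PSF set")
        if len(self.psfs) != len(self.u_positions):
            raise ValueError("number of PSFs and u positions differ")
        if len(self.u_positions) >= 2 and not np.all(np.diff(self.u_positions) > 0):
            raise ValueError("u positions must be strictly increasing")
        for p in self.psfs:
            if np.any(np.asarray(p) < -1e-12):
                raise ValueError("PSFs must be nonnegative")


def sigma_profile(model: LSFMPSFModel, u) -> np.ndarray | float:
    """Axial sheet spread sigma(u) = alpha * sqrt(1 + (beta*u)^2), in voxels."""
    u = np.asarray(u, dtype=float)
    out = model.alpha * np.sqrt(1.0 + (model.beta * u) ** 2)
    return float(out) if out.ndim == 0 else out


_BASE_CACHE: dict[tuple, np.ndarray] = {}


def base_imaging_psf(kernel_shape: tuple[int, int, int], na: float,
                     defocus_rate: float) -> np.ndarray:
    """Space-invariant detection PSF: pupil disc with per-slice defocus phase.

    Slice ``dz`` of the kernel is the squared modulus of the inverse Fourier
    transform of ``exp(i*2*pi*defocus_rate*dz*rho^2)`` on a disc of radius
    ``na`` (relative to the inscribed pupil).  Normalized to unit total sum.
    """
    key = (kernel_shape, round(na, 12), round(defocus_rate, 12))
    if key in _BASE_CACHE:
        return _BASE_CACHE[key]
    kx, ky, kz = kernel_shape
    pad = 2
    lx, ly = pad * kx, pad * ky
    uy = (np.arange(ly) - ly / 2.0) / (ly / 2.0)
    ux = (np.arange(lx) - lx / 2.0) / (lx / 2.0)
    xx, yy = np.meshgrid(ux, uy, indexing="ij")
    rho2 = (xx * xx + yy * yy) / na**2
    mask = rho2 <= 1.0
    cz = (kz - 1) / 2.0
    dz = np.arange(kz) - cz
    phases = defocus_rate * dz[:, None, None] * rho2[None]
    pupil = np.exp(2j * np.pi * phases) * mask[None]
    # sub-pixel tilt so the pattern centre lands on the kernel's geometric centre
    sy = (kx - 1) / 2.0 - (lx // 2 - (lx - kx) // 2)
    sx = (ky - 1) / 2.0 - (ly // 2 - (ly - ky) // 2)
    tilt = -(sx / 2.0) * (yy / na) - (sy / 2.0) * (xx / na)
    pupil = pupil * np.exp(2j * np.pi * tilt)[None]
    fieldz = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(pupil, axes=(1, 2))),
                             axes=(1, 2))
    inten = fieldz.real**2 + fieldz.imag**2
    x0 = (lx - kx) // 2
    y0 = (ly - ky) // 2
    psf = np.transpose(inten[:, x0:x0 + kx, y0:y0 + ky], (1, 2, 0))
    psf = psf / psf.sum()
    _BASE_CACHE[key] = psf
    return psf


def _base_psf(model: LSFMPSFModel) -> np.ndarray:
    if model.base_psf is not None:
        hp = np.asarray(model.base_psf, dtype=float)
        return hp / hp.sum()
    return base_imaging_psf(model.kernel_shape, model.na, model.defocus_rate)


def lsfm_psf(model: LSFMPSFModel, u: float) -> np.ndarray:
    """Light-sheet PSF kernel at focus coordinate ``u`` (kernel axes dx,dy,dz).

    The imaging PSF is weighted along z by the sheet's Gaussian profile with
    its printed 1/(sigma*sqrt(2*pi)) normalization; no re-normalization, so
    total flux genuinely drops once the sheet outgrows the kernel support.
    """
    sig = sigma_profile(model, u)
    if sig <= 0:
        raise ValueError("sigma must be positive")
    hp = _base_psf(model)
    kz = hp.shape[2]
    dz = np.arange(kz) - (kz - 1) / 2.0
    env = np.exp(-0.5 * (dz / sig) ** 2) / (sig * math.sqrt(2.0 * math.pi))
    return hp * env[None, None, :]


def interpolate_psf(u_query: float, psf_set: AxialPSFSet) -> np.ndarray:
    """Convex combination of the two measured PSFs bracketing ``u_query``.

    Outside the measured range the nearest endpoint PSF is returned (clamp).
    """
    u = psf_set.u_positions
    if u_query <= u[0]:
        return np.asarray(psf_set.psfs[0], dtype=float)
    if u_query >= u[-1]:
        return np.asarray(psf_set.psfs[-1], dtype=float)
    k = int(np.searchsorted(u, u_query, side="right") - 1)
    t = (u_query - u[k]) / (u[k + 1] - u[k])
    return ((1.0 - t) * np.asarray(psf_set.psfs[k], dtype=float)
            + t * np.asarray(psf_set.psfs[k + 1], dtype=float))


def _kernel_for_slice(psfs, u: float) -> np.ndarray:
    if isinstance(psfs, LSFMPSFModel):
        return lsfm_psf(psfs, u)
    if isinstance(psfs, AxialPSFSet):
        return interpolate_psf(u, psfs)
    raise TypeError("psfs must be an LSFMPSFModel or AxialPSFSet")


class SheetOperator:
    """Precomputed linear operator for sheet convolution and its adjoint.

    ``u`` is measured from the waist, taken at the centre of the first axis.
    All axes are periodic.
    """

    def __init__(self, shape: tuple[int, int, int], psfs):
        self.shape = tuple(shape)
        nx, ny, nz = self.shape
        waist = (nx - 1) / 2.0
        kernels = [_kernel_for_slice(psfs, ux - waist) for ux in range(nx)]
        kx, ky, kz = kernels[0].shape
        if ky > ny or kz > nz:
            raise ValueError(f"kernel {kernels[0].shape} larger than volume "
                             f"{self.shape} in (y, z)")
        self.kx = kx
        cx, cy, cz = (kx - 1) // 2, (ky - 1) // 2, (kz - 1) // 2
        self.x_offsets = np.arange(kx) - cx
        k_hat = np.empty((nx, kx, ny, nz), dtype=complex)
        for ux, ker in enumerate(kernels):
            emb = np.zeros((kx, ny, nz))
            emb[:, :ky, :kz] = ker
            emb = np.roll(emb, (-cy, -cz), axis=(1, 2))
            k_hat[ux] = np.fft.fft2(emb, axes=(1, 2))
        self.k_hat = k_hat

    def apply(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        if g.shape != self.shape:
            raise ValueError(f"expected volume of shape {self.shape}, got {g.shape}")
        nx = self.shape[0]
        out = np.zeros(self.shape)
        for ux in range(nx):
            sl = g[ux]
            if not np.any(sl):
                continue
            g_hat = np.fft.fft2(sl)
            contrib = np.fft.ifft2(g_hat[None] * self.k_hat[ux], axes=(1, 2)).real
            rows = (ux + self.x_offsets) % nx
            np.add.at(out, rows, contrib)
        return out

    def adjoint(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if f.shape != self.shape:
            raise ValueError(f"expected volume of shape {self.shape}, got {f.shape}")
        nx = self.shape[0]
        f_hat = np.fft.fft2(f, axes=(1, 2))
        out = np.empty(self.shape)
        for ux in range(nx):
            rows = (ux + self.x_offsets) % nx
            acc = np.sum(np.conj(self.k_hat[ux]) * f_hat[rows], axis=0)
            out[ux] = np.fft.ifft2(acc).real
        return out


def sheet_convolve(g: np.ndarray, psfs) -> np.ndarray:
    """Blur a volume with the laterally varying light-sheet forward model."""
    return SheetOperator(np.asarray(g).shape, psfs).apply(g)


def sheet_correlate(f: np.ndarray, psfs) -> np.ndarray:
    """Adjoint of :func:`sheet_convolve`."""
    return SheetOperator(np.asarray(f).shape, psfs).adjoint(f)


def sheet_blur_direct(g: np.ndarray, psfs) -> np.ndarray:
    """Brute-force 3D superposition oracle: place one kernel per voxel."""
    g = np.asarray(g, dtype=float)
    nx, ny, nz = g.shape
    waist = (nx - 1) / 2.0
    embedded = {}
    out = np.zeros_like(g)
    for ux, vy, tz in zip(*np.nonzero(g)):
        if ux not in embedded:
            ker = _kernel_for_slice(psfs, ux - waist)
            kx, ky, kz = ker.shape
            emb = np.zeros_like(g)
            emb[:kx, :ky, :kz] = ker
            embedded[ux] = np.roll(
                emb, (-(kx - 1) // 2, -(ky - 1) // 2, -(kz - 1) // 2),
                axis=(0, 1, 2))
        out += g[ux, vy, tz] * np.roll(embedded[ux], (ux, vy, tz), axis=(0, 1, 2))
    return out


def sheet_deconvolve(f: np.ndarray, psfs, cfg: SolverConfig | None = None,
                     x0: np.ndarray | None = None) -> DeblurResult:
    """TV-regularized least-squares inversion of sheet convolution."""
    op = psfs if isinstance(psfs, SheetOperator) else SheetOperator(np.asarray(f).shape, psfs)
    return iterative_least_squares(f, op.apply, op.adjoint, cfg=cfg, x0=x0)


# ---------------------------------------------------------------------------
# calibration-stack fitting and resolution measurement
# ---------------------------------------------------------------------------

def detect_beads(volume: np.ndarray, threshold_rel: float = 0.2,
                 min_separation: int = 5) -> list[tuple[int, int, int]]:
    """3D local maxima above ``threshold_rel * max`` with a separation filter."""
    volume = np.asarray(volume, dtype=float)
    footprint = maximum_filter(volume, size=min_separation)
    peaks = np.argwhere((volume == footprint) & (volume > threshold_rel * volume.max()))
    peaks = sorted(map(tuple, peaks), key=lambda p: -volume[p])
    kept: list[tuple[int, int, int]] = []
    for p in peaks:
        if all(np.linalg.norm(np.subtract(p, q)) >= min_separation for q in kept):
            kept.append(p)
    return kept


def fit_lsfm_model(
    cal_stack: np.ndarray,
    template: LSFMPSFModel | None = None,
    threshold_rel: float = 0.2,
    min_separation: int = 5,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.3, 10.0), (0.0, 1.0)),
) -> LSFMPSFModel:
    """Fit (alpha, beta) so the model PSFs match beads in a calibration stack.

    Beads are detected as 3D local maxima; crops around them are compared with
    model PSFs at their ``u`` (with closed-form per-bead amplitudes), and the
    summed squared residual is minimized with bounded L-BFGS.
    """
    cal_stack = np.asarray(cal_stack, dtype=float)
    template = template or LSFMPSFModel(alpha=2.0, beta=0.05)
    beads = detect_beads(cal_stack, threshold_rel, min_separation)
    if not beads:
        raise ValueError("no beads detected in the calibration stack")
    kx, ky, kz = template.kernel_shape
    hx, hy, hz = kx // 2, ky // 2, kz // 2
    nx, ny, nz = cal_stack.shape
    waist = (nx - 1) / 2.0
    crops = []
    us = []
    for (bx, by, bz) in beads:
        if (bx - hx < 0 or bx + hx + 1 > nx or by - hy < 0 or by + hy + 1 > ny
                or bz - hz < 0 or bz + hz + 1 > nz):
            continue
        crops.append(cal_stack[bx - hx:bx + hx + 1, by - hy:by + hy + 1,
                               bz - hz:bz + hz + 1])
        us.append(bx - waist)
    if not crops:
        raise ValueError("all detected beads are too close to the stack border")
    if len({round(u) for u in us}) < 2:
        warnings.warn("beads span (almost) a single u position; beta is weakly "
                      "constrained")

    def loss(params: np.ndarray) -> float:
        alpha, beta = params
        model = replace(template, alpha=float(alpha), beta=float(beta))
        total = 0.0
        for crop, u in zip(crops, us):
            p = lsfm_psf(model, u)
            a = float(np.sum(crop * p) / max(np.sum(p * p), 1e-300))
            total += float(np.sum((crop - a * p) ** 2))
        return total

    res = optimize.minimize(loss, x0=np.array([template.alpha, template.beta]),
                            method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-16, "gtol": 1e-14,
                                     "eps": 1e-7, "maxiter": 500})
    alpha, beta = res.x
    return replace(template, alpha=float(alpha), beta=float(beta))


def measure_fwhm(volume: np.ndarray, location: tuple[int, int, int],
                 axis: int) -> float:
    """Full width at half maximum of the 1D profile through a peak.

    Linear interpolation of the half-maximum crossings on either side of the
    peak; raises if the profile does not fall below half max within the volume
    (peak at the edge).
    """
    volume = np.asarray(volume, dtype=float)
    idx = list(location)
    profile = volume[tuple(
        slice(None) if ax == axis else idx[ax] for ax in range(volume.ndim))]
    p = int(location[axis])
    peak = profile[p]
    if peak <= 0:
        raise ValueError("no peak at the requested location")
    half = peak / 2.0

    def _cross(direction: int) -> float:
        i = p
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] <= half:
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - p) + frac
            i = j
        raise ValueError("profile does not fall below half max inside the volume")

    return _cross(+1) + _cross(-1)
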