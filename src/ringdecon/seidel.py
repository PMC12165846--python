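"""Pupil functions and field-dependent PSFs from primary Seidel coefficients.

A rotationally symmetric imaging system is summarised by five primary
(fourth-order) wavefront aberration weights, in waves: sphere, coma,
astigmatism, field curvature and distortion.  For a point source at normalized
field height ``H`` and field angle ``theta`` the wavefront error over the unit
pupil disc ``(rho, phi)`` is

    W = sphere*rho^4
      + coma*H*rho^3*cos(phi - theta)
      + astigmatism*H^2*rho^2*cos^2(phi - theta)
      + field_curvature*H^2*rho^2
      + distortion*H^3*rho*cos(phi - theta)

and the PSF is the squared modulus of the inverse Fourier transform of the
pupil function ``exp(i*2*pi*W)`` on the disc support.  The unit disc is
inscribed in the (padded) computation grid, which pins the diffraction-limited
spot width at ~2 px regardless of grid size.

Field rotation is exact: it enters through ``cos(phi - theta)`` in the
polynomial, never through lossy image-domain rotation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SeidelCoefficients",
    "OpticalGrid",
    "PupilPhase",
    "seidel_wavefront",
    "render_psf",
    "render_canvas_psf",
    "render_radial_psf_stack",
    "canvas_side",
    "centroid_shift",
]

_COEFF_NAMES = ("sphere", "coma", "astigmatism", "field_curvature", "distortion")


@dataclass(frozen=True)
class SeidelCoefficients:
    """The five primary Seidel aberration weights, in waves."""

    sphere: float = 0.0
    coma: float = 0.0
    astigmatism: float = 0.0
    field_curvature: float = 0.0
    distortion: float = 0.0

    def __post_init__(self) -> None:
        for name in _COEFF_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name!r} is not finite: {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _COEFF_NAMES], dtype=float)

    @property
    def norm(self) -> float:
        """Euclidean norm of the five weights; the 'aberration magnitude'."""
        return float(np.linalg.norm(self.as_array()))

    @classmethod
    def from_array(cls, arr) -> "SeidelCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 coefficients, got shape {arr.shape}")
        return cls(*(float(v) for v in arr))

    @classmethod
    def from_json(cls, path) -> "SeidelCoefficients":
        data = json.loads(Path(path).read_text())
        return cls(**{n: float(data[n]) for n in _COEFF_NAMES})

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({n: getattr(self, n) for n in _COEFF_NAMES}, indent=2) + "\n")


@dataclass(frozen=True)
class OpticalGrid:
    """Discrete geometry shared by every PSF render.

    ``n`` is the sensor side length in pixels; the pupil is computed on a
    padded ``pad_factor * n`` grid to avoid wraparound.  ``max_field_radius``
    (default: the image half-diagonal) normalizes field heights so the corner
    of the field of view has ``H = 1``.
    """

    n: int
    pad_factor: int = 2
    max_field_radius: float | None = None
    pixel_pitch: float = 1.0
    pupil_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError(f"image side must be >= 8 px, got {self.n}")
        if self.pad_factor < 1:
            raise ValueError(f"pad_factor must be >= 1, got {self.pad_factor}")
        if self.max_field_radius is not None and not self.max_field_radius > 0:
            raise ValueError("max_field_radius must be positive")
        if not 0 < self.pupil_fraction <= 1:
            raise ValueError("pupil_fraction must lie in (0, 1]")

    @property
    def pupil_samples(self) -> int:
        return self.n * self.pad_factor

    @property
    def r_max(self) -> float:
        if self.max_field_radius is not None:
            return float(self.max_field_radius)
        return self.n * math.sqrt(2.0) / 2.0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.n - 1) / 2.0, (self.n - 1) / 2.0)

    def field_height(self, r: float) -> float:
        return float(r) / self.r_max


@dataclass
class PupilPhase:
    """Wavefront error map (waves) over the unit pupil disc."""

    phase: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if np.iscomplexobj(self.phase):
            raise ValueError("pupil phase must be real-valued")
        self.phase = np.where(self.mask, self.phase, 0.0)


class _PupilBasis:
    """Cached per-grid monomials of the pupil coordinates.

    ``fraction`` is the pupil disc diameter as a fraction of the grid side;
    1.0 (the default, disc inscribed in the grid) gives a ~2 px diffraction
    core, which samples the intensity pattern at twice its Nyquist band —
    adequate for the forward model, where both sides share the aliasing, but
    symmetry oracles should use 0.5 for alias-free sampling.
    """

    _cache: dict[tuple[int, float], "_PupilBasis"] = {}

    def __init__(self, side: int, fraction: float = 1.0):
        u = (np.arange(side) - side / 2.0) / (fraction * side / 2.0)
        yy, xx = np.meshgrid(u, u, indexing="ij")
        rho2 = xx * xx + yy * yy
        self.side = side
        self.fraction = fraction
        self.mask = rho2 <= 1.0
        self.xhat = np.where(self.mask, xx, 0.0)   # rho*cos(phi)
        self.yhat = np.where(self.mask, yy, 0.0)   # rho*sin(phi)
        self.rho2 = np.where(self.mask, rho2, 0.0)
        self.rho4 = self.rho2 * self.rho2
        self.energy = float(self.mask.sum()) / side**2  # Parseval: total |E|^2

    @classmethod
    def get(cls, side: int, fraction: float = 1.0) -> "_PupilBasis":
        key = (side, round(fraction, 12))
        if key not in cls._cache:
            if len(cls._cache) > 8:
                cls._cache.clear()
            cls._cache[key] = cls(side, fraction)
        return cls._cache[key]

    def wavefront(self, coeffs: SeidelCoefficients, h: float, theta: float,
                  tilt: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        """W in waves; ``tilt`` is the (t_y, t_x) from :func:`_tilt_for_shift`."""
        q = self.xhat * math.cos(theta) + self.yhat * math.sin(theta)
        w = (coeffs.sphere * self.rho4
             + coeffs.coma * h * self.rho2 * q
             + coeffs.astigmatism * h**2 * q * q
             + coeffs.field_curvature * h**2 * self.rho2
             + coeffs.distortion * h**3 * q)
        ty, tx = tilt
        if tx != 0.0 or ty != 0.0:
            # one wave of rho*cos tilt shifts by -2/fraction px: scale so the
            # requested pixel shift is exact for any pupil fraction
            w = w + (tx * self.fraction) * self.xhat \
                + (ty * self.fraction) * self.yhat
        return w


def seidel_wavefront(coeffs: SeidelCoefficients, field_height: float,
                     field_angle: float, grid: OpticalGrid) -> PupilPhase:
    """Primary-aberration wavefront map for a source at (H, theta)."""
    if not 0.0 <= field_height <= 1.0:
        raise ValueError(f"field height must lie in [0, 1], got {field_height}")
    basis = _PupilBasis.get(grid.pupil_samples, grid.pupil_fraction)
    w = basis.wavefront(coeffs, field_height, field_angle)
    return PupilPhase(phase=w, mask=basis.mask.copy())


def _tilt_for_shift(dy: float, dx: float) -> tuple[float, float]:
    """Tilt coefficients (waves of rho*sin, rho*cos) shifting the PSF by (dy, dx) px.

    One wave of ``rho*cos(phi)`` tilt across the inscribed pupil shifts the
    intensity pattern by -2 px along x (FFT shift theorem), independent of the
    grid size.
    """
    return (-dy / 2.0, -dx / 2.0)


def _fields_to_psfs(phases: np.ndarray, basis: _PupilBasis) -> np.ndarray:
    """Batch of wavefronts (..., L, L) in waves -> unit-energy intensity PSFs."""
    pupil = np.exp(2j * np.pi * phases) * basis.mask
    field = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(pupil, axes=(-2, -1))),
                            axes=(-2, -1))
    psf = (field.real**2 + field.imag**2)
    return psf / basis.energy  # total energy over the full grid == 1


def _crop(arr: np.ndarray, side: int, start: int) -> np.ndarray:
    return arr[..., start:start + side, start:start + side]


def render_psf(coeffs: SeidelCoefficients, source_radius: float,
               source_angle: float, grid: OpticalGrid) -> np.ndarray:
    """Sensor-frame PSF image for a point source at polar position (r, theta).

    The unaberrated image point lands at ``center + r*(sin, cos)(theta)``.
    Returned array is ``n x n``, nonnegative, normalized to unit sum over the
    crop.
    """
    if source_radius > grid.r_max * (1 + 1e-9):
        raise ValueError(
            f"source radius {source_radius} exceeds max field radius {grid.r_max}")
    if source_radius < 0:
        raise ValueError("source radius must be nonnegative")
    n, l = grid.n, grid.pupil_samples
    basis = _PupilBasis.get(l, grid.pupil_fraction)
    h = grid.field_height(source_radius)
    # target position within the n x n crop, relative to the natural FFT center
    start = (l - n) // 2
    natural = l // 2 - start
    dy = grid.center[0] + source_radius * math.sin(source_angle) - natural
    dx = grid.center[1] + source_radius * math.cos(source_angle) - natural
    w = basis.wavefront(coeffs, h, source_angle, tilt=_tilt_for_shift(dy, dx))
    psf = _crop(_fields_to_psfs(w, basis), n, start)
    s = psf.sum()
    if s <= 0:
        raise ValueError("rendered PSF has no energy inside the sensor frame")
    return psf / s


def canvas_side(grid: OpticalGrid) -> int:
    """Side of the square canvas covering the full polar disc.

    Shares the sensor's parity so the canvas pixel grid aligns with the image
    pixel grid (both centred at ``(side-1)/2``).
    """
    c = 2 * math.ceil(grid.r_max) + 1
    if (c - grid.n) % 2:
        c += 1
    return c


def render_canvas_psf(coeffs: SeidelCoefficients, source_radius: float,
                      source_angle: float, grid: OpticalGrid) -> np.ndarray:
    """Full-disc PSF on the extended canvas, normalized by *total* energy.

    Unlike :func:`render_psf` the result is not re-normalized after cropping:
    the canvas retains the whole pattern, so kernels for sources near (or
    beyond) the sensor edge stay physically weighted.  This is the kernel
    representation the ring-convolution stack uses.
    """
    if source_radius > grid.r_max * (1 + 1e-9) or source_radius < 0:
        raise ValueError(f"source radius {source_radius} outside [0, {grid.r_max}]")
    c = canvas_side(grid)
    l = 2 * c
    basis = _PupilBasis.get(l, grid.pupil_fraction)
    h = grid.field_height(source_radius)
    start = (c + 1) // 2
    natural = l // 2 - start
    c0 = (c - 1) / 2.0
    dy = c0 + source_radius * math.sin(source_angle) - natural
    dx = c0 + source_radius * math.cos(source_angle) - natural
    w = basis.wavefront(coeffs, h, source_angle, tilt=_tilt_for_shift(dy, dx))
    return _crop(_fields_to_psfs(w, basis), c, start)


def render_radial_psf_stack(coeffs: SeidelCoefficients, grid: OpticalGrid,
                            num_radii: int):
    """PSFs along one radial line (theta = 0) at K uniformly spaced radii.

    Returns a :class:`~ringdecon.lri.RadialPSFStack` whose kernels live on the
    extended canvas (see :func:`render_canvas_psf`).
    """
    from .lri import RadialPSFStack

    if num_radii < 2:
        raise ValueError(f"need at least 2 radii, got {num_radii}")
    radii = np.linspace(0.0, grid.r_max, num_radii)
    c = canvas_side(grid)
    l = 2 * c
    basis = _PupilBasis.get(l, grid.pupil_fraction)
    start = (c + 1) // 2
    natural = l // 2 - start
    c0 = (c - 1) / 2.0
    psfs = np.empty((num_radii, c, c))
    chunk = max(1, int(2.5e7 // (l * l)))  # bound peak memory of the batch FFT
    for lo in range(0, num_radii, chunk):
        hi = min(lo + chunk, num_radii)
        phases = np.empty((hi - lo, l, l))
        for j in range(lo, hi):
            phases[j - lo] = basis.wavefront(
                coeffs, grid.field_height(radii[j]), 0.0,
                tilt=_tilt_for_shift(c0 - natural, c0 + radii[j] - natural))
        psfs[lo:hi] = _crop(_fields_to_psfs(phases, basis), c, start)
    return RadialPSFStack(psfs=psfs, radii=radii, grid=grid)


def centroid_shift(coeffs: SeidelCoefficients, field_height: float,
                   pupil_fraction: float = 1.0) -> float:
    """First-order radial centroid displacement of the PSF, in pixels.

    Over the uniform unit disc only the odd terms have a nonzero mean phase
    gradient; the displacement is ``-(2/f)*(coma*H + distortion*H^3)`` px
    along the field direction (negative = toward the optical center), where
    ``f`` is the pupil fraction.
    """
    h = field_height
    return -(2.0 / pupil_fraction) * (coeffs.coma * h + coeffs.distortion * h**3)
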