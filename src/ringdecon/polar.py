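"""Resampling between Cartesian images and (angle x radius) polar grids.

The polar grid is the domain in which revolution-invariant blur becomes a 1D
circular convolution over the angular axis.  Both directions use bilinear
interpolation; each direction also exposes its exact adjoint (the transpose of
the underlying sparse linear map), which the iterative solvers rely on.

Conventions
-----------
* angle axis: ``M`` uniform samples on ``[0, 2*pi)``; row ``m`` is the angle
  ``phi_m = 2*pi*m/M``.
* radius axis: ``K`` uniform samples on ``[0, max_radius]``.
* a polar sample ``(m, k)`` reads the Cartesian image at
  ``(row, col) = center + r_k * (sin(phi_m), cos(phi_m))``.
* the default Cartesian center is the geometric pixel center
  ``((N-1)/2, (N-1)/2)`` so even image sides are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarGridSpec",
    "PolarImage",
    "default_polar_spec",
    "to_polar",
    "from_polar",
    "to_polar_adjoint",
    "from_polar_adjoint",
]


@dataclass(frozen=True)
class PolarGridSpec:
    """Geometry of an (angle x radius) polar grid about an optical center."""

    num_angles: int
    num_radii: int
    center: tuple[float, float]
    max_radius: float

    def __post_init__(self) -> None:
        if self.num_angles < 4:
            raise ValueError(f"need at least 4 angular samples, got {self.num_angles}")
        if self.num_radii < 2:
            raise ValueError(f"need at least 2 radial samples, got {self.num_radii}")
        if not self.max_radius > 0:
            raise ValueError(f"max_radius must be positive, got {self.max_radius}")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.num_angles) * (2.0 * np.pi / self.num_angles)

    @property
    def radii(self) -> np.ndarray:
        return np.linspace(0.0, self.max_radius, self.num_radii)

    @property
    def dr(self) -> float:
        return self.max_radius / (self.num_radii - 1)

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.num_angles


@dataclass
class PolarImage:
    """An image resampled onto an (angle x radius) grid (angle-major)."""

    values: np.ndarray
    spec: PolarGridSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.spec.num_angles, self.spec.num_radii)
        if self.values.shape != expected:
            raise ValueError(f"polar array shape {self.values.shape} != spec {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("polar image contains non-finite values")


def default_polar_spec(n: int, center: tuple[float, float] | None = None,
                       max_radius: float | None = None) -> PolarGridSpec:
    """Default polar grid for an ``n x n`` image.

    ``K = ceil(n*sqrt(2)/2) + 1`` radii gives ~1 px radial spacing out to the
    image corners; ``M`` is the smallest multiple of 4 at or above
    ``ceil(2*pi*max_radius)`` so the outermost ring is not angularly
    undersampled.
    """
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    if max_radius is None:
        max_radius = n * math.sqrt(2.0) / 2.0
    num_radii = math.ceil(n * math.sqrt(2.0) / 2.0) + 1
    m = math.ceil(2.0 * np.pi * max_radius)
    num_angles = 4 * math.ceil(m / 4)
    return PolarGridSpec(num_angles=num_angles, num_radii=num_radii,
                         center=center, max_radius=max_radius)


# ---------------------------------------------------------------------------
# bilinear gather / scatter primitives (mutually adjoint by construction)
# ---------------------------------------------------------------------------

def _bilinear_weights(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]):
    """Corner indices and weights of bilinear samples; out-of-bounds -> weight 0."""
    n0, n1 = shape
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    idx = []
    for dr_, dc_, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr_
        cc = c0 + dc_
        valid = (rr >= 0) & (rr < n0) & (cc >= 0) & (cc < n1)
        idx.append((np.where(valid, rr, 0), np.where(valid, cc, 0), np.where(valid, w, 0.0)))
    return idx


def _gather(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    out = np.zeros(rows.shape, dtype=float)
    for rr, cc, w in _bilinear_weights(rows, cols, image.shape):
        out += w * image[rr, cc]
    return out


def _scatter(values: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    for rr, cc, w in _bilinear_weights(rows, cols, shape):
        np.add.at(out, (rr.ravel(), cc.ravel()), (w * values).ravel())
    return out


def _polar_sample_coords(spec: PolarGridSpec) -> tuple[np.ndarray, np.ndarray]:
    phi = spec.angles[:, None]
    r = spec.radii[None, :]
    rows = spec.center[0] + r * np.sin(phi)
    cols = spec.center[1] + r * np.cos(phi)
    return rows, cols


def _cartesian_sample_coords(n: int, spec: PolarGridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fractional (angle, radius) indices of each Cartesian pixel in the polar grid.

    The angular index wraps modulo M; radial indices beyond K-1 are flagged by
    returning them unchanged (the gather zero-fills them).
    """
    rr, cc = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    dy = rr - spec.center[0]
    dx = cc - spec.center[1]
    r = np.hypot(dy, dx)
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    a_idx = phi / spec.dtheta
    k_idx = r / spec.dr
    return a_idx, k_idx


# ---------------------------------------------------------------------------
# public transforms
# ---------------------------------------------------------------------------

def to_polar(image: np.ndarray, spec: PolarGridSpec) -> PolarImage:
    """Resample a square image onto the polar grid (bilinear gather)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1] or image.size == 0:
        raise ValueError(f"expected a non-empty square image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    rows, cols = _polar_sample_coords(spec)
    return PolarImage(_gather(image, rows, cols), spec)


def to_polar_adjoint(pimg: PolarImage, n: int) -> np.ndarray:
    """Exact transpose of :func:`to_polar` (scatter back to an n x n image)."""
    rows, cols = _polar_sample_coords(pimg.spec)
    return _scatter(pimg.values, rows, cols, (n, n))


def from_polar(pimg: PolarImage, n: int) -> np.ndarray:
    """Resample a polar image back onto an ``n x n`` Cartesian grid.

    Per-pixel bilinear gather at each pixel's (angle, radius) coordinates; the
    angular axis is treated as periodic, radii beyond the grid give zero.
    """
    spec = pimg.spec
    a_idx, k_idx = _cartesian_sample_coords(n, spec)
    return _polar_gather(pimg.values, a_idx, k_idx)


def from_polar_adjoint(image: np.ndarray, spec: PolarGridSpec) -> PolarImage:
    """Exact transpose of :func:`from_polar` (scatter into the polar grid)."""
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    a_idx, k_idx = _cartesian_sample_coords(n, spec)
    return PolarImage(_polar_scatter(image, a_idx, k_idx, spec), spec)


def _polar_corner_terms(a_idx: np.ndarray, k_idx: np.ndarray, m: int, k: int):
    a0 = np.floor(a_idx).astype(np.int64)
    k0 = np.floor(k_idx).astype(np.int64)
    fa = a_idx - a0
    fk = k_idx - k0
    for da, dk, w in (
        (0, 0, (1 - fa) * (1 - fk)),
        (0, 1, (1 - fa) * fk),
        (1, 0, fa * (1 - fk)),
        (1, 1, fa * fk),
    ):
        aa = np.mod(a0 + da, m)
        kk = k0 + dk
        valid = (kk >= 0) & (kk < k)
        yield aa, np.where(valid, kk, 0), np.where(valid, w, 0.0)


def _polar_gather(values: np.ndarray, a_idx: np.ndarray, k_idx: np.ndarray) -> np.ndarray:
    m, k = values.shape
    out = np.zeros(a_idx.shape, dtype=float)
    for aa, kk, w in _polar_corner_terms(a_idx, k_idx, m, k):
        out += w * values[aa, kk]
    return out


def _polar_scatter(values: np.ndarray, a_idx: np.ndarray, k_idx: np.ndarray,
                   spec: PolarGridSpec) -> np.ndarray:
    m, k = spec.num_angles, spec.num_radii
    out = np.zeros((m, k), dtype=float)
    for aa, kk, w in _polar_corner_terms(a_idx, k_idx, m, k):
        np.add.at(out, (aa.ravel(), kk.ravel()), (w * values).ravel())
    return out
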