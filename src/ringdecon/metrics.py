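"""Small image-quality metrics used across the package and its tests."""

from __future__ import annotations

import numpy as np

__all__ = ["rel_l2", "rel_mse", "psnr", "snr_db", "total_gradient"]


def rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    """Relative L2 distance ||a - b|| / ||b||."""
    return float(np.linalg.norm(np.ravel(a) - np.ravel(b)) / np.linalg.norm(np.ravel(b)))


def rel_mse(a: np.ndarray, b: np.ndarray) -> float:
    """Relative mean-squared error mean((a-b)^2) / mean(b^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.mean((a - b) ** 2) / np.mean(b**2))


def psnr(estimate: np.ndarray, truth: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; peak defaults to the truth's maximum."""
    truth = np.asarray(truth, dtype=float)
    if peak is None:
        peak = float(truth.max())
    mse = float(np.mean((np.asarray(estimate, dtype=float) - truth) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def snr_db(signal: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR: 10*log10(mean signal power / noise variance)."""
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noisy, dtype=float) - signal
    return float(10.0 * np.log10(np.mean(signal**2) / np.mean(noise**2)))


def total_gradient(image: np.ndarray) -> float:
    """Sum of absolute forward differences; the sharpness surrogate."""
    image = np.asarray(image, dtype=float)
    gx = np.diff(image, axis=-1)
    gy = np.diff(image, axis=-2)
    return float(np.abs(gx).sum() + np.abs(gy).sum())
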