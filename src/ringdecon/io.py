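"""File I/O: TIFF / raw-array images and volumes, run configs, provenance.

Images load as float64 in memory and write as 32-bit float TIFF.  Multi-page
TIFF stacks map to volumes with the page axis first (the light-sheet focus
axis by default; declare otherwise in the run config).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["read_image", "write_image", "read_volume", "write_volume",
           "RunConfig", "write_provenance"]

_RAW_SUFFIXES = {".npy"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _check_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path}: RGB(A) input; extract a single channel first (multicolor "
            "data is deblurred per channel)")
    return arr


def read_image(path) -> np.ndarray:
    """Read a single 2D grayscale image (.tif/.tiff or .npy) as float."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    elif path.suffix.lower() in _RAW_SUFFIXES:
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    arr = _check_gray(np.asarray(arr), path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return arr.astype(float)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, image)
    elif path.suffix.lower() in _RAW_SUFFIXES:
        np.save(path, image)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")


def read_volume(path) -> np.ndarray:
    """Read a 3D volume (multi-page TIFF, page axis first, or .npy)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    elif path.suffix.lower() in _RAW_SUFFIXES:
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    return arr.astype(float)


def write_volume(path, volume: np.ndarray) -> None:
    path = Path(path)
    volume = np.asarray(volume, dtype=np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, volume)
    elif path.suffix.lower() in _RAW_SUFFIXES:
        np.save(path, volume)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")


@dataclass
class RunConfig:
    """Run settings shared by the CLI subcommands; YAML-serializable."""

    n: int = 64
    pad_factor: int = 2
    num_radii: int | None = None
    max_iters: int = 300
    step_size: float = 0.1
    tv_weight: float = 1e-4
    nonneg: bool = True
    tol: float = 1e-6
    seed: int = 0
    freeze_distortion: bool = False
    flat_field: bool = True
    crop_border: int = 0
    normalize: bool = True
    hot_pixel_filter: bool = False
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extras = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extras.update(extras)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__
                if k != "extras"}
        data.update(self.extras)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_provenance(path, command: str, config: dict) -> None:
    """JSON record that makes a CLI run reproducible."""
    try:
        from importlib.metadata import version
        ver = version("ringdecon")
    except Exception:
        ver = "unknown"
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "tool": "rdm",
        "version": ver,
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
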