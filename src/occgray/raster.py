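"""Raster I/O: read sRGB images into [0, 1] floats, write 8-bit gray/RGB.

Reads PNG/TIFF/JPEG through imageio.  8-bit inputs divide by 255 exactly;
16-bit inputs are down-converted with a warning; alpha channels are dropped.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .dwca import quantize

__all__ = ["read_rgb", "write_gray", "write_rgb"]


def read_rgb(path) -> np.ndarray:
    """Read an image file as an (H, W, 3) float array in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit input down-converted to 8-bit range", UserWarning)
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")


def write_gray(path, gray) -> None:
    """Quantize a [0, 1] gray raster to 8 bits and write PNG/TIFF."""
    iio.imwrite(Path(path), quantize(gray))


def write_rgb(path, image) -> None:
    """Quantize a [0, 1] RGB raster to 8 bits and write PNG/TIFF."""
    iio.imwrite(Path(path), quantize(np.asarray(image)))
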