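"""Image and array I/O helpers: PNG/TIFF in [0, 1], zero-padding to square."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image", "pad_to_square"]


def pad_to_square(image: np.ndarray) -> np.ndarray:
    """Zero-pad the smaller dimension (centered) so the raster is square."""
    h, w = image.shape[:2]
    if h == w:
        return image
    size = max(h, w)
    pad_h = size - h
    pad_w = size - w
    pads = [(pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)]
    if image.ndim == 3:
        pads.append((0, 0))
    return np.pad(image, pads)


def load_image(path: str | Path, square: bool = True) -> np.ndarray:
    """Read PNG/TIFF as float RGB in [0, 1]; grayscale is replicated."""
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return pad_to_square(arr) if square else arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).astype(np.uint8))
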