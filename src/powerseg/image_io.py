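"""Reading and writing grayscale images and binary masks.

Images are read with :mod:`imageio` and scaled to [0, 1] by their dtype
range (255 for 8-bit, 65535 for 16-bit); RGB inputs are collapsed to
luminance.  Masks are written as 8-bit PNG/TIFF with foreground 255, so
``read_image(write_mask(...)) > 0.5`` round-trips a mask exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_mask", "ImageInfo"]

logger = logging.getLogger("powerseg")

# Rec. 709 luminance weights, as used by standard grayscale conversion.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class ImageInfo(NamedTuple):
    """Provenance of a loaded image: source dtype, bit depth, was it RGB."""

    dtype: str
    bit_depth: int
    was_color: bool


def read_image(path, return_info: bool = False):
    """Load a grayscale (or RGB → luminance) image scaled to [0, 1].

    Parameters
    ----------
    path : str or Path
        PNG/TIFF/JPEG file, 8- or 16-bit.
    return_info : bool
        Also return an :class:`ImageInfo` with the original bit depth.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises various backend errors
        raise ValueError(f"could not read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image file {path} is empty")

    was_color = False
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count in {path}: {arr.shape}")
        arr = arr.astype(float) @ _LUMA
        was_color = True
        logger.info("converted RGB input %s to luminance", path)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")

    dtype = np.asarray(raw).dtype
    if dtype == np.uint8:
        scale, bits = 255.0, 8
    elif dtype == np.uint16:
        scale, bits = 65535.0, 16
    elif np.issubdtype(dtype, np.floating):
        scale, bits = 1.0, 0
    else:
        scale, bits = float(np.iinfo(dtype).max), int(np.iinfo(dtype).bits)
    img = np.clip(arr.astype(float) / scale, 0.0, 1.0)
    if return_info:
        return img, ImageInfo(str(dtype), bits, was_color)
    return img


def write_mask(path, mask) -> None:
    """Write a binary mask as an 8-bit grayscale image (foreground = 255)."""
    path = Path(path)
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    out = (m.astype(bool) * np.uint8(255)).astype(np.uint8)
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise ValueError(f"could not write mask to {path}: {exc}") from exc
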