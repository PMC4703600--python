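"""Raster I/O and color-space conversions.

Images are plain numpy arrays: an RGB image is an ``(H, W, 3)`` uint8 array,
a grayscale image an ``(H, W)`` uint8 array.  All conversions here are
full-range 8-bit; the luminance transform is the hardware-friendly
``Y = R/4 + G/2 + B/4`` used throughout the enhancement and colorization
pipeline (evaluated exactly, with a single rounding step, so that white maps
to 255 and achromatic pixels are fixed points).
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "rgb_to_luminance",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "rgb_to_lab",
    "as_gray",
    "as_rgb",
]

_SUPPORTED_EXT = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W, 3)`` uint8 RGB image."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.dtype != np.uint8:
        if np.any(img < 0) or np.any(img > 255):
            raise ValueError("channel values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W)`` uint8 grayscale image."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected an (H, W) grayscale array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.dtype != np.uint8:
        if np.any(img < 0) or np.any(img > 255):
            raise ValueError("gray values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an 8-bit RGB or grayscale array.

    16-bit inputs are rescaled to 8-bit (``round(v * 255 / 65535)``); an alpha
    channel is dropped with a logged warning.  3-channel files yield an
    ``(H, W, 3)`` array, 1-channel files an ``(H, W)`` array.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise IOError(f"unsupported image format {ext!r} for {path!r} "
                      f"(supported: PNG, JPEG, TIFF)")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise IOError(f"cannot read image {path!r}: {exc}") from exc

    if arr.dtype == np.uint16:
        arr = np.rint(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise IOError(f"unsupported pixel type {arr.dtype} in {path!r}")

    if arr.ndim == 3 and arr.shape[2] in (2, 4):
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, : arr.shape[2] - 1]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 2:
        return as_gray(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return as_rgb(arr)
    raise IOError(f"unsupported image layout {arr.shape} in {path!r}")


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB or grayscale array to *path* (format from the extension).

    PNG is lossless: ``read_image(write_image(x))`` round-trips pixel-exactly.
    """
    img = as_rgb(img) if np.ndim(img) == 3 else as_gray(img)
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"cannot write {path!r}: directory {parent!r} does not exist")
    try:
        iio.imwrite(path, img)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def rgb_to_luminance(img: np.ndarray) -> np.ndarray:
    """Luminance ``Y = R/4 + G/2 + B/4``, rounded once to the nearest integer.

    The sum is evaluated exactly as ``(R + 2G + B) / 4`` before the single
    rounding step, so white maps to 255 and every achromatic pixel
    ``(v, v, v)`` maps to ``v``.
    """
    img = as_rgb(img)
    r = img[..., 0].astype(np.uint32)
    g = img[..., 1].astype(np.uint32)
    b = img[..., 2].astype(np.uint32)
    # (R + 2G + B) / 4 with round-half-away-from-zero on the exact quotient
    y = (r + 2 * g + b + 2) >> 2
    return y.astype(np.uint8)


# Full-range ITU-R BT.601 RGB <-> YCbCr.
_YCBCR_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


def rgb_to_ycbcr(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-range BT.601 YCbCr planes ``(Y, Cb, Cr)`` as float64 arrays.

    Neutral chroma sits at 128; an achromatic pixel has Cb = Cr = 128.
    """
    img = as_rgb(img).astype(np.float64)
    planes = np.tensordot(img, _YCBCR_FWD.T, axes=([2], [0]))
    y = planes[..., 0]
    cb = planes[..., 1] + 128.0
    cr = planes[..., 2] + 128.0
    return y, cb, cr


def ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycbcr`; recovers RGB within ±1 per channel."""
    inv = np.linalg.inv(_YCBCR_FWD)
    stacked = np.stack([np.asarray(y), np.asarray(cb) - 128.0,
                        np.asarray(cr) - 128.0], axis=-1)
    rgb = np.tensordot(stacked, inv.T, axes=([2], [0]))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIE L*a*b* planes under sRGB primaries / D65 white, L in [0, 100]."""
    img = as_rgb(img)
    lab = _skcolor.rgb2lab(img)
    return lab[..., 0], lab[..., 1], lab[..., 2]
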