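"""Grayscale image and binary mask containers with TIFF/PNG I/O.

Conventions used throughout the package:

* intensities live on the 0–255 scale and are stored as floats internally;
* arrays are 0-based, row-major ``(row, col)``; row 0 is the top of the
  B-scan (vitreous side);
* a 1024 × 992 px scan therefore has ``width == 1024`` and ``height == 992``.

RGB inputs are collapsed to luma with the Rec. 601 weights
(0.299 R + 0.587 G + 0.114 B); 16-bit inputs are rescaled linearly to 0–255.
Multi-frame TIFFs are rejected rather than silently reading frame 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "rgb_to_gray",
]

_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster on the 0–255 intensity scale."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite pixel values")
        if px.min() < 0 or px.max() > 255:
            raise FormatError(
                f"pixel values must lie in [0, 255], got range "
                f"[{px.min():g}, {px.max():g}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1}-valued mask over the same pixel domain as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"mask must be 2-D and non-empty, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask values must be in {{0, 1}}, got {vals[:10]}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an ``(H, W, 3)`` array to luma with Rec. 601 weights.

    Idempotent on already-gray content: if R == G == B the output equals
    the common channel (weights sum to 1).
    """
    return np.asarray(rgb, dtype=np.float64)[..., :3] @ _REC601


def _load_raster(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise FormatError(
                    f"multi-frame TIFF not supported: {path} has "
                    f"{len(tif.pages)} frames"
                )
            arr = tif.pages[0].asarray()
    else:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) != 1:
                raise FormatError(f"multi-frame image not supported: {path}")
            arr = np.asarray(im)
    return arr


def _to_gray_255(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise FormatError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")

    if arr.dtype == np.uint8:
        out = arr.astype(np.float64)
    elif arr.dtype == np.uint16:
        out = arr.astype(np.float64) * (255.0 / 65535.0)
    else:
        raise FormatError(f"unsupported bit depth/dtype {arr.dtype} in {path}")

    if out.ndim == 3:
        out = rgb_to_gray(out)
    return out


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read an 8- or 16-bit TIFF/PNG raster as a :class:`GrayImage`."""
    arr = _load_raster(path)
    return GrayImage(_to_gray_255(arr, os.fspath(path)))


def write_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write as 8-bit (values rounded half-up and clamped to [0, 255])."""
    data = np.clip(np.floor(img.pixels + 0.5), 0, 255).astype(np.uint8)
    _write_u8(data, path)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a raster as a binary mask: any nonzero pixel counts as 1."""
    arr = _load_raster(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return BinaryMask((np.asarray(arr) != 0).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit {0, 255} for viewability; round-trips losslessly."""
    _write_u8((mask.pixels * 255).astype(np.uint8), path)


def _write_u8(data: np.ndarray, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)
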