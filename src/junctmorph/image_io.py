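"""Raster image I/O, thresholding and the PSNR quality-control metric.

All modules share one coordinate convention: 0-based ``(row, col)`` pixel
coordinates with the row index increasing downward.  Intensities are kept in
the native integer range of the image (8- or 16-bit); nothing here rescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "RasterImage",
    "BinaryMask",
    "load_image",
    "save_image",
    "apply_threshold",
    "compute_psnr",
    "add_gaussian_noise",
]

_DTYPE_FOR_DEPTH = {8: np.uint8, 16: np.uint16}


class RasterImage:
    """A single-channel grayscale intensity grid.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.  ``uint8``/``uint16`` arrays
        fix the bit depth; other numeric arrays require an explicit
        ``bit_depth`` and must already lie inside ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.  Inferred from the dtype when omitted.
    """

    def __init__(self, pixels, bit_depth: int | None = None):
        arr = np.asarray(pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if bit_depth is None:
            if arr.dtype == np.uint8:
                bit_depth = 8
            elif arr.dtype == np.uint16:
                bit_depth = 16
            else:
                raise ValueError(
                    "bit_depth must be given for non-uint8/uint16 input"
                )
        if bit_depth not in _DTYPE_FOR_DEPTH:
            raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
        max_value = 2**bit_depth - 1
        if arr.dtype in (np.uint8, np.uint16):
            if int(arr.max(initial=0)) > max_value:
                raise ValueError("intensities exceed the stated bit depth")
            arr = arr.astype(_DTYPE_FOR_DEPTH[bit_depth])
        else:
            a = np.asarray(arr, dtype=float)
            if not np.isfinite(a).all():
                raise ValueError("intensities must be finite")
            if a.min() < 0 or a.max() > max_value:
                raise ValueError("intensities outside [0, max_value]")
            arr = np.rint(a).astype(_DTYPE_FOR_DEPTH[bit_depth])
        self.pixels: np.ndarray = arr
        self.bit_depth: int = int(bit_depth)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RasterImage({self.height}x{self.width}, "
            f"{self.bit_depth}-bit)"
        )


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


def load_image(path, channel: int | None = None) -> RasterImage:
    """Read a TIFF or PNG raster, optionally selecting one plane/channel.

    Multi-plane TIFFs are indexed along the first axis; multi-channel PNGs
    along the last.  Bit depth is preserved; no rescaling is performed.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such image file: {p}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(p)
        channel_axis = 0
    elif suffix == ".png":
        arr = iio.imread(p)
        channel_axis = -1
    else:
        raise IOError(f"unsupported raster format: {suffix}")
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{p.name} has multiple planes; a channel index is required"
            )
        n = arr.shape[channel_axis]
        if not (0 <= channel < n):
            raise ValueError(f"channel {channel} out of range [0, {n})")
        arr = arr[channel] if channel_axis == 0 else arr[..., channel]
    elif arr.ndim != 2:
        raise IOError(f"{p.name}: expected a 2-D raster, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return RasterImage(arr, 8)
    if arr.dtype == np.uint16:
        return RasterImage(arr, 16)
    raise IOError(f"{p.name}: unsupported pixel type {arr.dtype}")


def save_image(path, image: RasterImage) -> None:
    """Write ``image`` to TIFF or PNG losslessly (bit depth preserved)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(p, image.pixels)
    elif suffix == ".png":
        iio.imwrite(p, image.pixels)
    else:
        raise IOError(f"unsupported raster format: {suffix}")


def apply_threshold(image: RasterImage, threshold: float) -> BinaryMask:
    """Mask of pixels whose intensity is *strictly greater* than ``threshold``.

    The strict inequality makes threshold 0 on an all-zero image yield an
    empty mask and gives the monotone behaviour mask(t2) <= mask(t1) for
    t1 < t2.
    """
    if not (0 <= threshold <= image.max_value):
        raise ValueError(
            f"threshold {threshold} outside [0, {image.max_value}]"
        )
    return BinaryMask(image.pixels > threshold)


def compute_psnr(reference: RasterImage, test: RasterImage) -> float:
    """Peak signal-to-noise ratio in dB between two equally shaped images.

    Returns ``math.inf`` for identical images (MSE 0): a perfect image is a
    quality-control pass, not an error.  Values above ~22 dB indicate the
    contrast needed for reliable automatic skeleton detection.
    """
    if reference.shape != test.shape:
        raise ValueError("PSNR requires images of identical shape")
    if reference.bit_depth != test.bit_depth:
        raise ValueError("PSNR requires images of identical bit depth")
    diff = reference.as_float() - test.as_float()
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(reference.max_value**2 / mse)


def add_gaussian_noise(
    image: RasterImage, sigma: float, seed: int
) -> RasterImage:
    """Add zero-mean Gaussian noise, clipping (not wrapping) to the bit range.

    Deterministic for a fixed ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return RasterImage(image.pixels.copy(), image.bit_depth)
    rng = np.random.default_rng(seed)
    noisy = image.as_float() + rng.normal(0.0, sigma, size=image.shape)
    np.clip(noisy, 0, image.max_value, out=noisy)
    return RasterImage(noisy, image.bit_depth)
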