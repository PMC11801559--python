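"""Reading, writing, normalizing and quantizing single-channel grayscale rasters.

All enhancement modules operate on :class:`NormalizedImage`; :class:`RawImage`
is the I/O boundary type. Normalization divides by the image's own observed
maximum by default (so the brightest pixel maps to exactly 1.0), with an
optional by-bit-depth alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RawImage",
    "NormalizedImage",
    "read_image",
    "write_image",
    "normalize",
    "to_octet",
    "quantize",
]


class DimensionError(ValueError):
    """Image shape violates a size precondition."""


class DegenerateImageError(ValueError):
    """Image content makes the requested operation undefined (e.g. all zeros)."""


@dataclass(frozen=True)
class RawImage:
    """Integer grayscale raster.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers.
    bit_depth
        8 or 16; all pixels must fit in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    max_value: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise DimensionError(f"image must be at least 2x2, got {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValueError("pixel values out of range for bit depth")
        object.__setattr__(self, "pixels", px.astype(dtype))
        object.__setattr__(self, "max_value", int(px.max()))

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
class NormalizedImage:
    """Real-valued raster with all values finite and in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise DimensionError(f"expected a 2-D raster, got ndim={v.ndim}")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise DimensionError(f"image must be at least 2x2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in normalized image")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("normalized values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


ImageLike = Union[RawImage, NormalizedImage]


def read_image(path: str | Path) -> RawImage:
    """Read a PNG/TIFF (or, if pydicom is installed, DICOM) file as grayscale.

    Multi-channel inputs are reduced to one channel by averaging; MURA files
    are sometimes stored as 3-channel grayscale so rejection would be hostile.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        arr = _read_dicom(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
        arr = np.round(arr)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DimensionError(f"unsupported image shape {arr.shape} in {path}")
    depth = 16 if arr.max() > 255 or arr.dtype.itemsize > 1 else 8
    return RawImage(pixels=arr.astype(np.uint16 if depth == 16 else np.uint8),
                    bit_depth=depth)


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("DICOM support requires the 'pydicom' extra") from exc
    return np.asarray(pydicom.dcmread(path).pixel_array)


def write_image(image: RawImage, path: str | Path) -> None:
    """Write a raw image losslessly (PNG or TIFF chosen by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.pixels)


def normalize(image: RawImage, by_depth: bool = False) -> NormalizedImage:
    """Map integer pixels onto [0, 1].

    By default divides by the image's own maximum intensity so that the result
    attains exactly 1. With ``by_depth=True`` divides by ``2**bit_depth - 1``
    instead.
    """
    if image.max_value <= 0:
        raise DegenerateImageError("cannot normalize an all-zero image")
    denom = float(2**image.bit_depth - 1) if by_depth else float(image.max_value)
    return NormalizedImage(values=image.pixels.astype(np.float64) / denom)


def quantize(values: np.ndarray, levels: int = 256) -> np.ndarray:
    """Round [0,1] reals onto integer levels, half away from zero."""
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be quantized")
    # np.floor(x + 0.5) is round-half-away-from-zero for non-negative x
    return np.floor(v * (levels - 1) + 0.5).astype(np.int64)


def to_octet(image: NormalizedImage) -> RawImage:
    """Quantize a normalized image to 8 bits without re-stretching.

    The mapping is ``round(values * 255)`` with half-away-from-zero rounding,
    so a maximum below 1.0 stays below 255 (max-preservation of the sharpening
    stage survives to the saved file).
    """
    return RawImage(pixels=quantize(image.values).astype(np.uint8), bit_depth=8)


def as_octet_array(image: ImageLike) -> np.ndarray:
    """Any image type -> float array on the 0-255 intensity scale."""
    if isinstance(image, NormalizedImage):
        return image.values * 255.0
    if image.bit_depth == 8:
        return image.pixels.astype(np.float64)
    return image.pixels.astype(np.float64) * (255.0 / (2**image.bit_depth - 1))
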