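"""Reading, writing and normalizing grayscale radiographic images.

All processing happens in floating point on the unit interval [0, 1]; stored
integer ranges [0, 2^bit_depth - 1] are linearly rescaled on load and
quantized (round-half-up) on save. DICOM rescale slope/intercept is applied
before normalization; window/level tags are ignored (the full dynamic range
is used). MONOCHROME1 images are inverted so that higher value = brighter.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np

from .exceptions import UnsupportedFormatError

__all__ = ["Image2D", "load_image", "save_image"]

_MIN_DIM = 16


@dataclasses.dataclass(frozen=True)
class Image2D:
    """A 2D real-valued intensity grid in [0, 1] with provenance metadata.

    The universal currency between pipeline stages: every stage consumes and
    produces one. Stages that can overshoot must clamp before constructing.
    """

    pixels: np.ndarray
    source_bit_depth: int = 16
    source_format: str = "synthetic"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D grid, got shape {px.shape}")
        if px.shape[0] < _MIN_DIM or px.shape[1] < _MIN_DIM:
            raise ValueError(f"image must be at least {_MIN_DIM}x{_MIN_DIM}, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]; clamp before constructing")
        if self.source_bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported source bit depth {self.source_bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        *,
        clip: bool = False,
        source_bit_depth: int = 16,
        source_format: str = "synthetic",
    ) -> "Image2D":
        """Wrap a float array, optionally clamping to [0, 1] first."""
        arr = np.asarray(arr, dtype=np.float64)
        if clip:
            arr = np.clip(arr, 0.0, 1.0)
        return cls(arr, source_bit_depth=source_bit_depth, source_format=source_format)


def _pixels_of(img) -> np.ndarray:
    """Accept an Image2D or a bare 2D array."""
    return img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)


def _load_dicom(path: Path) -> Image2D:
    import pydicom

    ds = pydicom.dcmread(os.fspath(path))
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: color DICOM is not supported")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    arr = arr * slope + intercept
    bits = int(getattr(ds, "BitsStored", 16))
    if bits <= 8:
        bits = 8
    elif bits <= 12:
        bits = 12
    else:
        bits = 16
    full_scale = float(2**bits - 1)
    arr = np.clip(arr / full_scale, 0.0, 1.0)
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        arr = 1.0 - arr
    return Image2D(arr, source_bit_depth=bits, source_format="dicom")


def _load_raster(path: Path) -> Image2D:
    import imageio.v3 as iio

    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3:
        raise UnsupportedFormatError(f"{path}: color images are not supported")
    if arr.dtype == np.uint8:
        bits = 8
    elif arr.dtype == np.uint16:
        bits = 16
    else:
        raise UnsupportedFormatError(f"{path}: unsupported pixel type {arr.dtype}")
    fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "png"
    pixels = arr.astype(np.float64) / float(2**bits - 1)
    return Image2D(pixels, source_bit_depth=bits, source_format=fmt)


def load_image(path) -> Image2D:
    """Read a grayscale single-frame raster (PNG/TIFF) or monochrome DICOM.

    Intensities are linearly rescaled from [0, 2^bit_depth - 1] to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path)
    try:
        return _load_raster(path)
    except UnsupportedFormatError:
        raise
    except Exception:
        # Raster readers reject DICOM payloads regardless of extension.
        try:
            return _load_dicom(path)
        except UnsupportedFormatError:
            raise
        except Exception as exc:
            raise IOError(f"could not read {path}: {exc}") from exc


def save_image(img: Image2D, path, bit_depth: int = 16) -> None:
    """Quantize to `bit_depth` (round-half-up) and write a lossless PNG/TIFF."""
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    px = _pixels_of(img)
    full_scale = float(2**bit_depth - 1)
    quantized = np.floor(px * full_scale + 0.5)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    try:
        iio.imwrite(os.fspath(path), quantized.astype(dtype))
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
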