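"""No-reference and reference-based image-quality metrics.

ENT — histogram entropy of the whole image, in bits by default (the scale on
which 8-bit radiographs top out at 8).

CII — contrast improvement index: the Michelson-style region contrast
C = (X_f - X_b) / (X_f + X_b) of the processed image divided by that of the
reference, with the foreground mask derived once from the reference (Otsu,
brighter class) and shared by both images so that CII(x, x) = 1 exactly.

EME — effective measure of enhancement: the image is split into an r x c
block grid and EME = mean over blocks of 20 ln(I_max / (I_min + c)) with a
small constant c guarding the division.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core_io import _pixels_of
from .exceptions import DegenerateReferenceError, InvalidMaskError

__all__ = ["MetricConfig", "MetricReport", "entropy", "region_contrast", "cii", "eme", "otsu_foreground"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MetricConfig:
    """Metric settings.

    ent_bins / ent_log_base : entropy histogram bins and log base (2 -> bits,
        "e" -> nats).
    eme_grid : (r, c) block grid for EME.
    eme_c : small constant in the EME contrast ratio (avoids division by 0).
    cii_mask_mode : "otsu_on_reference" or "provided_mask".
    """

    ent_bins: int = 256
    ent_log_base: object = 2
    eme_grid: tuple[int, int] = (8, 8)
    eme_c: float = 1e-4
    cii_mask_mode: str = "otsu_on_reference"

    def __post_init__(self) -> None:
        if self.ent_bins < 2:
            raise ValueError("ent_bins must be >= 2")
        if self.ent_log_base not in (2, "e", math.e):
            raise ValueError("ent_log_base must be 2 or 'e'")
        if self.eme_grid[0] < 1 or self.eme_grid[1] < 1:
            raise ValueError("eme_grid entries must be >= 1")
        if self.eme_c <= 0:
            raise ValueError("eme_c must be > 0")
        if self.cii_mask_mode not in ("otsu_on_reference", "provided_mask"):
            raise ValueError(f"unknown cii_mask_mode {self.cii_mask_mode!r}")


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """ENT/CII/EME for one enhanced image; optional externally computed extras."""

    ent: float
    cii: float
    eme: float
    brisque: float | None = None
    total_variation: float | None = None

    def is_finite(self) -> bool:
        return all(math.isfinite(v) for v in (self.ent, self.cii, self.eme))


def entropy(img, cfg: MetricConfig | None = None) -> float:
    """Histogram entropy over equal-width bins on [0, 1]."""
    cfg = cfg or MetricConfig()
    arr = _pixels_of(img)
    counts, _ = np.histogram(arr, bins=cfg.ent_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / arr.size
    ent_nats = float(-(p * np.log(p)).sum())
    return ent_nats / math.log(2.0) if cfg.ent_log_base == 2 else ent_nats


def region_contrast(img, foreground_mask) -> float:
    """C = (X_f - X_b) / (X_f + X_b) over a boolean foreground mask."""
    arr = _pixels_of(img)
    mask = np.asarray(foreground_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise InvalidMaskError("mask shape does not match image")
    if not mask.any() or mask.all():
        raise InvalidMaskError("mask needs >= 1 foreground and >= 1 background pixel")
    x_f = float(arr[mask].mean())
    x_b = float(arr[~mask].mean())
    if x_f + x_b == 0.0:
        return 0.0
    return (x_f - x_b) / (x_f + x_b)


def otsu_foreground(reference) -> np.ndarray:
    """Otsu threshold on the reference; foreground = the brighter class."""
    from skimage.filters import threshold_otsu

    arr = _pixels_of(reference)
    return arr > threshold_otsu(arr)


def cii(processed, reference, cfg: MetricConfig | None = None, mask=None) -> float:
    """Contrast improvement index C_processed / C_reference.

    Under "otsu_on_reference" the mask is computed once on the reference and
    applied to both images; under "provided_mask" the caller supplies it.
    """
    cfg = cfg or MetricConfig()
    if cfg.cii_mask_mode == "provided_mask" or mask is not None:
        if mask is None:
            raise InvalidMaskError("cii_mask_mode 'provided_mask' requires a mask")
    else:
        mask = otsu_foreground(reference)
    c_ref = region_contrast(reference, mask)
    if c_ref == 0.0:
        raise DegenerateReferenceError("reference image has zero region contrast")
    return region_contrast(processed, mask) / c_ref


def eme(img, cfg: MetricConfig | None = None) -> float:
    """Mean over an r x c block grid of 20 ln(I_max / (I_min + c)).

    Blocks with I_max = 0 would give ln 0; their contrast ratio is floored
    at eme_c (logged once per call).
    """
    cfg = cfg or MetricConfig()
    arr = _pixels_of(img)
    r, c = cfg.eme_grid
    if arr.shape[0] < r or arr.shape[1] < c:
        raise ValueError(f"image {arr.shape} smaller than EME grid {cfg.eme_grid}")
    total = 0.0
    floored = 0
    for rows in np.array_split(arr, r, axis=0):
        for block in np.array_split(rows, c, axis=1):
            i_max = float(block.max())
            i_min = float(block.min())
            if i_max == 0.0:
                cr = cfg.eme_c
                floored += 1
            else:
                cr = i_max / (i_min + cfg.eme_c)
            total += 20.0 * math.log(cr)
    if floored:
        logger.info("EME: floored %d all-zero block(s) at CR = %g", floored, cfg.eme_c)
    return total / (r * c)
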