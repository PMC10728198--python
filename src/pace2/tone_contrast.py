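"""Tone and contrast operators: gamma correction and CLAHE.

Gamma correction is the power-law map T(l) = l_max (l / l_max)^gamma with
l_max the image maximum, so the transform adapts to the occupied dynamic
range; gamma < 1 brightens, gamma > 1 darkens, gamma = 1 is the identity.

CLAHE partitions the image into a grid of contextual regions, clips each
region's histogram at a fraction of its pixel count, redistributes the
clipped excess uniformly over all bins in a single pass, builds the
equalization mapping from the clipped CDF, and applies the mappings with
bilinear interpolation between the four surrounding region centers (edge
and corner pixels fall back to the nearest available mappings).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import Image2D, _pixels_of
from .exceptions import InvalidConfigError

__all__ = ["ToneConfig", "gamma_correct", "clahe", "region_equalization_maps"]


@dataclasses.dataclass(frozen=True)
class ToneConfig:
    """Gamma and CLAHE settings.

    gamma : power-law exponent (> 0), grid-searched over 0.5..2.0.
    clip_limit : CLAHE clip as a fraction of the per-region pixel count.
    tiles : contextual-region grid (rows, cols).
    bins : histogram bins per region.
    """

    gamma: float = 1.0
    clip_limit: float = 0.01
    tiles: tuple[int, int] = (4, 4)
    bins: int = 256

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0 < self.clip_limit <= 1):
            raise ValueError("clip_limit must be in (0, 1]")
        if self.tiles[0] < 2 or self.tiles[1] < 2:
            raise ValueError("tiles must be at least 2x2")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


def gamma_correct(img, gamma: float) -> np.ndarray:
    """T(l) = l_max (l / l_max)^gamma; the zero image maps to itself."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    arr = _pixels_of(img)
    l_max = float(arr.max())
    if l_max == 0.0:
        return np.zeros_like(arr)
    return l_max * np.clip(arr / l_max, 0.0, 1.0) ** gamma


def _interp_weights(positions: np.ndarray, centers: np.ndarray):
    """Neighboring tile indices and blend fraction for each pixel coordinate."""
    n = len(centers)
    j = np.searchsorted(centers, positions)
    i1 = np.clip(j, 0, n - 1)
    i0 = np.clip(j - 1, 0, n - 1)
    span = centers[i1] - centers[i0]
    frac = np.where(span > 0, (positions - centers[i0]) / np.where(span == 0, 1.0, span), 0.0)
    return i0, i1, np.clip(frac, 0.0, 1.0)


def region_equalization_maps(img, cfg: ToneConfig | None = None):
    """Per-region clipped-CDF lookup tables plus region-center coordinates.

    Returns (mappings, centers_y, centers_x, bin_idx) where mappings has
    shape (tile_rows, tile_cols, bins) and each mappings[i, j] is the
    monotone bin -> output map for that contextual region.
    """
    cfg = cfg or ToneConfig()
    arr = _pixels_of(img)
    h_img, w_img = arr.shape
    tr, tc = cfg.tiles
    row_parts = np.array_split(np.arange(h_img), tr)
    col_parts = np.array_split(np.arange(w_img), tc)
    if min(len(p) for p in row_parts) < 2 or min(len(p) for p in col_parts) < 2:
        raise InvalidConfigError(
            f"{tr}x{tc} tiles on a {h_img}x{w_img} image give regions smaller than 2x2"
        )

    bins = cfg.bins
    bin_idx = np.minimum((arr * bins).astype(np.intp), bins - 1)

    mappings = np.empty((tr, tc, bins))
    centers_y = np.empty(tr)
    centers_x = np.empty(tc)
    for i, rows in enumerate(row_parts):
        centers_y[i] = 0.5 * (rows[0] + rows[-1])
        for j, cols in enumerate(col_parts):
            centers_x[j] = 0.5 * (cols[0] + cols[-1])
            block = bin_idx[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
            npix = block.size
            hist = np.bincount(block.ravel(), minlength=bins).astype(np.float64)
            ceiling = cfg.clip_limit * npix
            excess = float(np.maximum(hist - ceiling, 0.0).sum())
            hist = np.minimum(hist, ceiling)
            hist += excess / bins
            mappings[i, j] = np.cumsum(hist) / npix
    return mappings, centers_y, centers_x, bin_idx


def clahe(img, cfg: ToneConfig | None = None) -> Image2D:
    """Contrast-limited adaptive histogram equalization on [0, 1] input."""
    cfg = cfg or ToneConfig()
    arr = _pixels_of(img)
    h_img, w_img = arr.shape
    mappings, centers_y, centers_x, bin_idx = region_equalization_maps(arr, cfg)

    iy0, iy1, fy = _interp_weights(np.arange(h_img, dtype=np.float64), centers_y)
    ix0, ix1, fx = _interp_weights(np.arange(w_img, dtype=np.float64), centers_x)
    iy0, iy1 = iy0[:, None], iy1[:, None]
    ix0, ix1 = ix0[None, :], ix1[None, :]
    fy = fy[:, None]
    fx = fx[None, :]

    out = (
        (1.0 - fy) * (1.0 - fx) * mappings[iy0, ix0, bin_idx]
        + (1.0 - fy) * fx * mappings[iy0, ix1, bin_idx]
        + fy * (1.0 - fx) * mappings[iy1, ix0, bin_idx]
        + fy * fx * mappings[iy1, ix1, bin_idx]
    )
    return Image2D.from_array(out, clip=True)
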