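"""Homomorphic filtering of the decomposition residue.

The residue carries the luminance background, so multiplicative
illumination inhomogeneity becomes additive after a log transform. A
high-frequency-emphasis (HEF) kernel — a Gaussian high-pass lifted to gain
g_L at DC and g_H at high frequency — then attenuates illumination while
boosting detail, and the exponential maps back. The result is affinely
rescaled to [0, 1].
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core_io import Image2D, _pixels_of

__all__ = ["HefConfig", "hef_kernel", "homomorphic_filter"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HefConfig:
    """High-frequency-emphasis filter settings.

    g_H : gain at high spatial frequency (the grid-searched parameter).
    g_L : gain at DC; < 1 attenuates (but does not erase) illumination.
    d0_frac : Gaussian cutoff D0 as a fraction of the smaller image dimension.
    log_offset : constant added before the log transform; continuous at 0.
    """

    g_H: float = 2.0
    g_L: float = 0.5
    d0_frac: float = 0.05
    log_offset: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.g_H >= self.g_L > 0):
            raise ValueError("require g_H >= g_L > 0")
        if not (0 < self.d0_frac < 0.5):
            raise ValueError("require 0 < d0_frac < 0.5")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")


def hef_kernel(height: int, width: int, cfg: HefConfig) -> np.ndarray:
    """Centered radial gain H(u,v) = (g_H - g_L)(1 - exp(-D^2/(2 D0^2))) + g_L.

    D is the distance from the spectral center (the DC bin after fftshift);
    D0 = d0_frac * min(height, width). Gain is g_L at DC and tends to g_H.
    """
    if height < 16 or width < 16:
        raise ValueError("kernel dimensions must be >= 16")
    cy, cx = height // 2, width // 2
    v = np.arange(height)[:, None] - cy
    u = np.arange(width)[None, :] - cx
    d2 = v.astype(np.float64) ** 2 + u.astype(np.float64) ** 2
    d0 = cfg.d0_frac * min(height, width)
    return (cfg.g_H - cfg.g_L) * (1.0 - np.exp(-d2 / (2.0 * d0 * d0))) + cfg.g_L


def _rescale_unit(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return np.clip(arr, 0.0, 1.0)
    return (arr - lo) / (hi - lo)


def homomorphic_filter(residue, cfg: HefConfig | None = None) -> Image2D:
    """log -> centered 2D FFT -> HEF gain -> inverse FFT -> exp -> rescale.

    Negative residue values (numerical noise from the subtractive
    decomposition) are clamped to 0 first. An all-zero residue short-circuits
    to an all-zero image.
    """
    cfg = cfg or HefConfig()
    arr = np.clip(_pixels_of(residue), 0.0, None)
    if not np.any(arr):
        logger.info("homomorphic filter: all-zero residue, returning zero image")
        return Image2D.from_array(np.zeros_like(arr))
    log_img = np.log(arr + cfg.log_offset)
    spectrum = np.fft.fftshift(np.fft.fft2(log_img))
    spectrum *= hef_kernel(*arr.shape, cfg)
    filtered = np.real(np.fft.ifft2(np.fft.ifftshift(spectrum)))
    out = np.exp(filtered) - cfg.log_offset
    return Image2D.from_array(_rescale_unit(out), clip=True)
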