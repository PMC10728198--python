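"""Non-local means denoising of the noise-dominated BIMFs.

Each output pixel is a weighted average over a search window, with weights
Gaussian in the squared Euclidean distance between the k x k patches around
the two pixels:

    W(x, y) = exp(-||N(x) - N(y)||^2 / (h^2 sigma^2))

h is the user bandwidth in 8-bit gray levels (default 3) and sigma the
noise standard deviation, estimated per component with a Laplacian MAD
estimator unless fixed in config. Patch distances are normalized per pixel
(divided by the patch area) so h and sigma are scale-free with respect to
patch size; components are shifted to non-negative and scaled to gray
levels [0, 255] for the distance computation, then returned on their
original scale. The search window is clipped to the image domain; patch
distances near borders use reflected padding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .core_io import _pixels_of
from .fabemd import BIMFStack

__all__ = ["NLMConfig", "estimate_sigma", "nlm_filter", "denoise_stack", "recombine"]

# 4-neighbor Laplacian scaled to unit response variance on white noise
# (sum of squared coefficients 4^2 + 4*1^2 = 20).
_LAPLACIAN = np.array([[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]]) / np.sqrt(20.0)
# Gaussian consistency constant: median(|N(0,1)|) = 0.6745.
_MAD_SCALE = 0.6745


@dataclasses.dataclass(frozen=True)
class NLMConfig:
    """Non-local means settings.

    patch_k : patch (similarity window) side length, odd, pixels.
    h : Gaussian bandwidth in 8-bit gray levels.
    search_radius : half-width of the search window (21x21 by default).
    sigma_mode : "mad_estimate" (Laplacian MAD per component) or "fixed".
    sigma_fixed : gray levels, used when sigma_mode == "fixed".
    """

    patch_k: int = 7
    h: float = 3.0
    search_radius: int = 10
    sigma_mode: str = "mad_estimate"
    sigma_fixed: float = 5.0

    def __post_init__(self) -> None:
        if self.patch_k < 3 or self.patch_k % 2 == 0:
            raise ValueError("patch_k must be odd and >= 3")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.search_radius < self.patch_k:
            raise ValueError("search_radius must be >= patch_k")
        if self.sigma_mode not in ("mad_estimate", "fixed"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")


def estimate_sigma(component) -> float:
    """Noise std in gray levels via median(|high-pass response|) / 0.6745.

    The component is scaled to [0, 255] gray levels and convolved with a
    variance-normalized Laplacian; the median absolute response is robust to
    the sparse structural content of a noise-dominated mode, and a high-pass
    kernel makes the estimate invariant to additive constants.
    """
    gray = _pixels_of(component) * 255.0
    detail = ndi.convolve(gray, _LAPLACIAN, mode="mirror")
    return float(np.median(np.abs(detail)) / _MAD_SCALE)


def nlm_filter(component, cfg: NLMConfig | None = None) -> np.ndarray:
    """Non-local means on one component, returned on its original scale.

    sigma = 0 (a structure-free or constant component) returns the input
    unchanged — there is no noise, and the weight would degenerate to 0/0.
    """
    cfg = cfg or NLMConfig()
    arr = _pixels_of(component)
    sigma = estimate_sigma(arr) if cfg.sigma_mode == "mad_estimate" else float(cfg.sigma_fixed)
    if sigma <= 0:
        return arr.copy()

    shift = float(arr.min())
    gray = (arr - shift) * 255.0
    h_img, w_img = gray.shape
    s = cfg.search_radius
    # Values come from a reflect-padded copy; the validity mask zeroes the
    # weight of positions that fall outside the true image domain.
    padded = np.pad(gray, s, mode="reflect")
    valid = np.pad(np.ones_like(gray), s, mode="constant", constant_values=0.0)
    inv_bw = 1.0 / (cfg.h * cfg.h * sigma * sigma)

    num = np.zeros_like(gray)
    den = np.zeros_like(gray)
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            shifted = padded[s + dy : s + dy + h_img, s + dx : s + dx + w_img]
            mask = valid[s + dy : s + dy + h_img, s + dx : s + dx + w_img]
            diff2 = (gray - shifted) ** 2
            dist = ndi.uniform_filter(diff2, size=cfg.patch_k, mode="mirror")
            w = np.exp(-dist * inv_bw) * mask
            num += w * shifted
            den += w
    out = num / den
    return out / 255.0 + shift


def denoise_stack(stack: BIMFStack, R: int, cfg: NLMConfig | None = None) -> np.ndarray:
    """I_E: NL-means the first R BIMFs, pass the rest through, and sum.

    The residue is excluded — its filtered version enters separately at
    recombination.
    """
    cfg = cfg or NLMConfig()
    if not (0 <= R < stack.K):
        raise ValueError("require 0 <= R < K")
    out = np.zeros(stack.source_dims)
    for i, bimf in enumerate(stack.bimfs):
        out += nlm_filter(bimf, cfg) if i < R else bimf
    return out


def recombine(I_E, I_HMF, beta: int) -> np.ndarray:
    """I_L = I_E + beta * I_HMF, clamped to [0, 1] (BIMF sums can overshoot)."""
    if beta not in (0, 1):
        raise ValueError("beta must be 0 or 1")
    a = _pixels_of(I_E)
    b = _pixels_of(I_HMF)
    if a.shape != b.shape:
        raise ValueError("I_E and I_HMF must share dimensions")
    return np.clip(a + beta * b, 0.0, 1.0)
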