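"""Seeded synthetic chest-like phantoms.

A phantom emulates the gross structure and the typical degradations of a
bedside chest radiograph on which the enhancement pipeline is exercised: a
mid-gray torso ellipse, two darker lung fields, sinusoidal rib bands, an
optional bright low-contrast "effusion" patch (the large bright region that
defeats naive equalization), an optional high-contrast device rectangle
with sharp edges, a multiplicative horizontal luminance ramp, Gaussian
sensor noise on the 8-bit gray scale, and salt-and-pepper impulses. Truth
masks for the lungs, effusion and device come back alongside the image so
contrast metrics can be evaluated against a known foreground.

Everything is driven by a single integer seed; the same spec always yields
a bitwise-identical image.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import Image2D
from .exceptions import InvalidSpecError

__all__ = ["EffusionSpec", "RibSpec", "DeviceSpec", "PhantomSpec", "generate_phantom"]


@dataclasses.dataclass(frozen=True)
class EffusionSpec:
    """Bright low-contrast patch: a disk of near-uniform high intensity."""

    center: tuple[float, float] = (0.58, 0.33)  # (y, x) as frame fractions
    radius: float = 0.09
    mean: float = 0.85
    internal_contrast: float = 0.03


@dataclasses.dataclass(frozen=True)
class RibSpec:
    """Periodic horizontal bands across the lung fields."""

    count: int = 6
    amplitude: float = 0.04


@dataclasses.dataclass(frozen=True)
class DeviceSpec:
    """High-contrast rectangle with sharp edges (external medical device)."""

    top_left: tuple[float, float] = (0.30, 0.72)
    size: tuple[float, float] = (0.18, 0.05)
    value: float = 0.95


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Scene geometry, degradation levels and the seed that fixes them all.

    noise_sigma is the Gaussian std on the 8-bit gray scale (to match the
    NL-means h = 3 gray-level convention); gradient_amp is the amplitude of
    the multiplicative horizontal luminance ramp (1 +/- gradient_amp).
    """

    seed: int = 42
    size: tuple[int, int] = (256, 256)
    gradient_amp: float = 0.2
    noise_sigma: float = 5.0
    impulse_frac: float = 0.002
    effusion: EffusionSpec | None = EffusionSpec()
    ribs: RibSpec | None = RibSpec()
    device: DeviceSpec | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.gradient_amp <= 0.5):
            raise ValueError("gradient_amp must be in [0, 0.5]")
        if self.noise_sigma < 0 or not (0 <= self.impulse_frac < 1):
            raise ValueError("invalid noise levels")
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError("phantom must be at least 16x16")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    if not (0 < cy - ay and cy + ay < 1 and 0 < cx - ax and cx + ax < 1):
        raise InvalidSpecError("ellipse extends outside the frame")
    yy = (np.arange(h)[:, None] / h - cy) / ay
    xx = (np.arange(w)[None, :] / w - cx) / ax
    return yy * yy + xx * xx <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[Image2D, dict[str, np.ndarray]]:
    """Render the clean scene, degrade it, and return image plus truth masks."""
    spec = spec or PhantomSpec()
    h, w = spec.size
    scene = np.full((h, w), 0.12)

    torso = _ellipse_mask(h, w, 0.50, 0.50, 0.44, 0.42)
    scene[torso] = 0.55
    lung_l = _ellipse_mask(h, w, 0.45, 0.31, 0.26, 0.15)
    lung_r = _ellipse_mask(h, w, 0.45, 0.69, 0.26, 0.15)
    lungs = lung_l | lung_r
    scene[lungs] = 0.30

    if spec.ribs is not None:
        y_norm = np.arange(h)[:, None] / h
        bands = spec.ribs.amplitude * np.sin(2.0 * np.pi * spec.ribs.count * y_norm)
        scene = np.where(lungs, scene + bands, scene)

    masks: dict[str, np.ndarray] = {"torso": torso, "lungs": lungs}

    if spec.effusion is not None:
        e = spec.effusion
        disk = _ellipse_mask(h, w, e.center[0], e.center[1], e.radius, e.radius)
        x_norm = np.arange(w)[None, :] / w
        texture = 0.5 * e.internal_contrast * np.sin(2.0 * np.pi * 8.0 * x_norm)
        scene = np.where(disk, e.mean + texture, scene)
        masks["effusion"] = disk
    else:
        masks["effusion"] = np.zeros((h, w), dtype=bool)

    if spec.device is not None:
        d = spec.device
        y0, x0 = d.top_left
        y1, x1 = y0 + d.size[0], x0 + d.size[1]
        if not (0 <= y0 < y1 <= 1 and 0 <= x0 < x1 <= 1):
            raise InvalidSpecError("device rectangle extends outside the frame")
        rect = np.zeros((h, w), dtype=bool)
        rect[int(y0 * h) : int(y1 * h), int(x0 * w) : int(x1 * w)] = True
        scene[rect] = d.value
        masks["device"] = rect
    else:
        masks["device"] = np.zeros((h, w), dtype=bool)

    ramp = 1.0 + spec.gradient_amp * (2.0 * np.arange(w)[None, :] / max(w - 1, 1) - 1.0)
    clean = np.clip(scene * ramp, 0.0, 1.0)

    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sigma / 255.0, size=(h, w))
    n_impulses = int(round(spec.impulse_frac * h * w))
    if n_impulses:
        flat = rng.choice(h * w, size=n_impulses, replace=False)
        vals = rng.random(n_impulses) < 0.5
        noisy.ravel()[flat] = vals.astype(np.float64)
    noisy = np.clip(noisy, 0.0, 1.0)

    return Image2D(noisy, source_bit_depth=8, source_format="synthetic"), masks
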