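"""Per-BIMF energies and the noise-dominated mode count R.

The energy of mode i is the plain sum of squares of its pixels. For a pure
white-noise input, successive mode energies follow a geometric decay law;
anchoring that law on the first mode (which is always noise-dominated)
gives a reference curve. Leading modes whose measured energy stays within a
multiplicative factor tau of the reference are classified as noise; the
first mode that departs upward marks the cutoff, and R counts the modes
before it. Those R modes are the ones handed to the non-local-means
denoiser.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fabemd import BIMFStack

__all__ = [
    "NoiseModelConfig",
    "EnergyProfile",
    "component_energies",
    "noise_energy_curve",
    "select_noise_order",
    "compute_energy_profile",
]


@dataclasses.dataclass(frozen=True)
class NoiseModelConfig:
    """Noise-only energy law: curve[i] = (E1 / beta_E) * rho**(-i), i >= 1.

    rho : geometric decay rate per mode (> 1).
    beta_E : first-mode normalizer.
    threshold_ratio : tau; a mode counts as informative once its energy
        exceeds tau times the noise-only reference.
    """

    rho: float = 2.01
    beta_E: float = 0.719
    threshold_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.rho <= 1:
            raise ValueError("rho must be > 1")
        if self.beta_E <= 0:
            raise ValueError("beta_E must be > 0")
        if self.threshold_ratio < 1:
            raise ValueError("threshold_ratio must be >= 1")


@dataclasses.dataclass(frozen=True)
class EnergyProfile:
    """Measured per-BIMF energies, the noise-only reference, and the cutoff."""

    energies: tuple
    noise_curve: tuple
    R: int
    threshold_ratio: float

    def __post_init__(self) -> None:
        K = len(self.energies)
        if len(self.noise_curve) != K:
            raise ValueError("energies and noise_curve must have equal length")
        if not (0 <= self.R < K):
            raise ValueError("require 0 <= R < K")


def component_energies(stack: BIMFStack) -> list[float]:
    """E_i = sum over pixels of BIMF_i**2 (zero-padded modes get 0)."""
    return [float(np.sum(b * b)) for b in stack.bimfs]


def noise_energy_curve(E1: float, K: int, cfg: NoiseModelConfig | None = None) -> list[float]:
    """Geometric noise-only reference anchored at the first mode's energy."""
    cfg = cfg or NoiseModelConfig()
    if E1 < 0:
        raise ValueError("E1 must be >= 0")
    curve = [float(E1)]
    for i in range(1, K):
        curve.append((E1 / cfg.beta_E) * cfg.rho ** (-i))
    return curve


def select_noise_order(energies, curve, cfg: NoiseModelConfig | None = None) -> int:
    """Count of leading modes whose energy stays within tau of the reference.

    R is one less than the first mode (second onward) whose energy exceeds
    tau * reference; if no mode departs, R = K - 1 (the strict R < K bound).
    A zero first-mode energy means no noise content at all: R = 0.
    """
    cfg = cfg or NoiseModelConfig()
    energies = list(energies)
    curve = list(curve)
    if len(energies) != len(curve):
        raise ValueError("energies and curve must have equal length")
    K = len(energies)
    if energies[0] == 0:
        return 0
    for i in range(1, K):
        if energies[i] > cfg.threshold_ratio * curve[i]:
            return i
    return K - 1


def compute_energy_profile(stack: BIMFStack, cfg: NoiseModelConfig | None = None) -> EnergyProfile:
    """Energies, reference curve and R for a decomposition in one call."""
    cfg = cfg or NoiseModelConfig()
    energies = component_energies(stack)
    curve = noise_energy_curve(energies[0], stack.K, cfg)
    R = select_noise_order(energies, curve, cfg)
    return EnergyProfile(
        energies=tuple(energies),
        noise_curve=tuple(curve),
        R=R,
        threshold_ratio=cfg.threshold_ratio,
    )
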