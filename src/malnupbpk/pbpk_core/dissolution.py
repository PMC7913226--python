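"""Dissolution kinetics for solid oral formulations.

Two laws are supported: an empirical Weibull profile parameterized by the
time to 50% dissolved and a shape factor, and Noyes–Whitney dissolution of
monodisperse spherical particles with a diffusion layer equal to the
(shrinking) particle radius.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Weibull:
    """fraction(t) = 1 - exp(-(t/scale)^shape) with fraction(t50) = 1/2."""

    t50_h: float
    shape: float

    def __post_init__(self):
        if self.t50_h <= 0 or self.shape <= 0:
            raise ValueError("t50 and shape must be positive")

    @property
    def scale(self) -> float:
        return self.t50_h / np.log(2.0) ** (1.0 / self.shape)

    def fraction(self, t):
        t = np.asarray(t, dtype=float)
        out = 1.0 - np.exp(-np.clip(t / self.scale, 0.0, None) ** self.shape)
        return out if out.ndim else float(out)

    def hazard(self, t: float) -> float:
        """Instantaneous dissolution rate constant at time t (1/h)."""
        if t <= 0.0:
            # finite start for shape >= 1; shape == 1 is first order
            return self.shape / self.scale if self.shape <= 1.0 else 0.0
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)


@dataclass(frozen=True)
class NoyesWhitney:
    """Diffusion-limited dissolution of monodisperse spheres.

    dM/dt = -(3 D / (rho r0^2)) * M0^(2/3) M^(1/3) * (Cs - C)
    with the diffusion-layer thickness equal to the particle radius.
    """

    radius_um: float
    diffusion_cm2_s: float = 5.0e-6
    density_mg_ml: float = 1200.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("particle radius must be positive")

    @property
    def rate_coefficient(self) -> float:
        """3 D / (rho r0^2) in mL/(mg h)."""
        d_cm2_h = self.diffusion_cm2_s * 3600.0
        r0_cm = self.radius_um * 1e-4
        return 3.0 * d_cm2_h / (self.density_mg_ml * r0_cm ** 2)

    def fraction(self, t, m0_mg: float = 1.0, solubility_mg_ml: float = 1.0):
        """Fraction dissolved under sink conditions (closed form)."""
        t = np.asarray(t, dtype=float)
        a = self.rate_coefficient * solubility_mg_ml  # 1/h on m/m0^(2/3) scale
        base = np.clip(1.0 - (2.0 / 3.0) * a * t, 0.0, None)
        out = 1.0 - base ** 1.5
        return out if out.ndim else float(out)


def dissolution_fraction(t, law, **kwargs):
    """Fraction of dose dissolved at time t under a dissolution law."""
    if np.any(np.asarray(t, dtype=float) < 0):
        raise ValueError("time must be non-negative")
    return law.fraction(t, **kwargs)
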