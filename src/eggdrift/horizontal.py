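"""Analytic horizontal diffusion-mortality kernel and the separable 3-D model.

With advection removed by working in the drifter-centroid frame, the
horizontal egg concentration after an instantaneous point release at time
t0 follows the anisotropic Fickian solution with exponential mortality:

    C(x, y, t) = exp(-x^2/(4 Kx t') - y^2/(4 Ky t') - mu t')
                 / (4 pi t' sqrt(Kx Ky)),          t' = t - t0,

with Kx, Ky the east-west and north-south diffusivities (m^2 h^-1) and mu
the hourly mortality.  The planar integral of C is exp(-mu t'): the
kernel carries both spread and survival.  Multiplying by the
unit-normalized vertical density C(z, t) gives the separable 3-D field

    C(x, y, z, t) = C(z, t) * C(x, y, t).

All times are hours; the release is at 19.00 local on the spawning night
(t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vertical import VerticalConcentration

__all__ = [
    "HorizontalParams",
    "Concentration3D",
    "horizontal_kernel",
    "survival_fraction",
    "concentration_3d",
    "convert_diffusivity_units",
    "mortality_per_day",
    "temperature_dependent_mortality",
]


@dataclass(frozen=True)
class HorizontalParams:
    """Kernel parameters: diffusivities in m^2 h^-1, mortality in h^-1."""

    Kx: float  # east-west diffusivity, m^2 h^-1
    Ky: float  # north-south diffusivity, m^2 h^-1
    mu: float = 0.0  # mortality, h^-1
    t0: float = 0.0  # release time, hours (0 = 19.00 local on spawning night)

    def __post_init__(self) -> None:
        if self.Kx <= 0 or self.Ky <= 0:
            raise ValueError("diffusivities must be positive")
        if self.mu < 0:
            raise ValueError("mortality must be non-negative")


def horizontal_kernel(x, y, t, p: HorizontalParams):
    """C(x, y, t), per m^2, for a unit point release at (0, 0, t0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    dt = t - p.t0
    if (dt <= 0).any():
        raise ValueError("kernel undefined at or before the release time t0")
    out = np.exp(
        -(x**2) / (4.0 * p.Kx * dt) - (y**2) / (4.0 * p.Ky * dt) - p.mu * dt
    ) / (4.0 * np.pi * dt * np.sqrt(p.Kx * p.Ky))
    return float(out) if out.ndim == 0 else out


def survival_fraction(t, mu: float):
    """Fraction surviving constant mortality ``mu`` (h^-1) for ``t`` hours."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("time must be non-negative")
    out = np.exp(-mu * t)
    return float(out) if out.ndim == 0 else out


@dataclass
class Concentration3D:
    """Separable 3-D field: scale * C(z, t) * C(x, y, t).

    ``scale`` is the total number of eggs released (1 = relative units);
    the triple integral over space is scale * exp(-mu (t - t0)).
    """

    horizontal: HorizontalParams
    vertical: VerticalConcentration
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def evaluate(self, x, y, z, t):
        """Concentration in eggs m^-3 (``scale`` eggs released) at (x,y,z,t)."""
        vert = self.vertical.interp(z, t)  # raises outside the gridded span
        horiz = horizontal_kernel(x, y, t, self.horizontal)
        return self.scale * vert * horiz


def concentration_3d(x, y, z, t, model: Concentration3D):
    """Functional alias for :meth:`Concentration3D.evaluate`."""
    return model.evaluate(x, y, z, t)


def convert_diffusivity_units(value):
    """m^2 h^-1 -> m^2 s^-1."""
    value = np.asarray(value, dtype=float)
    if (value < 0).any():
        raise ValueError("diffusivity must be non-negative")
    out = value / 3600.0
    return float(out) if out.ndim == 0 else out


def mortality_per_day(mu_per_hour: float) -> float:
    """h^-1 -> day^-1."""
    if mu_per_hour < 0:
        raise ValueError("mortality must be non-negative")
    return mu_per_hour * 24.0


def temperature_dependent_mortality(temp_c: float, a: float = 0.03, b: float = 0.18) -> float:
    """Expected daily egg mortality at temperature ``temp_c`` (deg C).

    Cross-species regression of field egg-mortality estimates on water
    temperature, mu = a * exp(b * T) day^-1; used to sanity-check fitted
    mortality against the literature expectation at the observed
    temperature.
    """
    return a * np.exp(b * temp_c)
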