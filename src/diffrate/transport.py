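"""Single-molecule transport closed forms.

Stokes-Einstein diffusion, compact-sphere radius from molecular weight,
mean nearest-neighbour separation, the critical reshuffle time, the 3D
Gaussian free-diffusion propagator, 1D first-passage probability, and the
hard-sphere (Maxwell-Boltzmann) collision frequency.

The critical reshuffle time ``t_c`` is the time at which the r.m.s.
diffusive displacement ``sqrt(2 D t)`` equals the mean molecular
separation ``L = C^(-1/3)``; the discrete rate models restart their
virtual concentration gradient every ``t_c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .constants import AVOGADRO, BOLTZMANN

__all__ = [
    "PropagatorQuery",
    "CollisionQuery",
    "stokes_einstein_D",
    "radius_from_molweight",
    "relative_diffusion",
    "mean_separation",
    "critical_time",
    "propagator_pdf",
    "propagator_radial_pdf",
    "first_passage_prob_1d",
    "collision_frequency_hard_sphere",
    "mean_thermal_speed",
]


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def stokes_einstein_D(temperature: float, viscosity: float, radius: float) -> float:
    """Diffusion coefficient of a sphere: ``D = k_B T / (6 pi eta r0)`` (m^2/s)."""
    _check_positive(temperature=temperature, viscosity=viscosity, radius=radius)
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * radius)


def radius_from_molweight(molecular_weight: float, density: float) -> float:
    """Compact-sphere radius from molecular weight (kg/mol) and neat density.

    Inverts ``Mw = (4/3) N_A pi r0^3 rho``; returns r0 in m.
    """
    _check_positive(molecular_weight=molecular_weight, density=density)
    return (3.0 * molecular_weight / (4.0 * math.pi * AVOGADRO * density)) ** (1.0 / 3.0)


def relative_diffusion(D_a: float, D_b: float) -> float:
    """Relative diffusion coefficient of a pair, ``D_A + D_B``.

    Pass 0 for an immobilized partner.
    """
    if D_a < 0 or D_b < 0:
        raise ValueError("diffusion coefficients must be non-negative")
    return D_a + D_b


def mean_separation(C):
    """Mean molecular separation ``L = C^(-1/3)`` (m) in a dilute solution."""
    _check_positive(number_concentration=C)
    out = np.asarray(C, dtype=float) ** (-1.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


def critical_time(D: float, C, fractal_correction: bool = False):
    """Nearest-neighbour reshuffle time ``t_c = 1 / (2 D C^(2/3))`` (s).

    With ``fractal_correction=True`` the value is halved, the empirical
    factor-of-2 bridging continuous diffusion with the discrete
    per-``t_c`` counting. Default off; the rate models apply their own
    explicit factor so that double counting is impossible.
    """
    _check_positive(D=D, number_concentration=C)
    out = 1.0 / (2.0 * D * np.asarray(C, dtype=float) ** (2.0 / 3.0))
    if fractal_correction:
        out = out / 2.0
    return float(out) if np.ndim(C) == 0 else out


@dataclass(frozen=True)
class PropagatorQuery:
    """Inputs to the 3D Gaussian propagator: elapsed time (s), diffusion
    coefficient (m^2/s), radius from the origin (m)."""

    elapsed_time: float
    diffusion_coefficient: float
    radius_from_origin: float

    def __post_init__(self) -> None:
        _check_positive(
            elapsed_time=self.elapsed_time,
            diffusion_coefficient=self.diffusion_coefficient,
        )
        if self.radius_from_origin < 0:
            raise ValueError("radius_from_origin must be >= 0")

    def pdf(self) -> float:
        return propagator_pdf(
            self.radius_from_origin, self.diffusion_coefficient, self.elapsed_time
        )

    def radial_pdf(self) -> float:
        return propagator_radial_pdf(
            self.radius_from_origin, self.diffusion_coefficient, self.elapsed_time
        )


def propagator_pdf(R, D: float, t: float):
    """Free 3D diffusion propagator ``(4 pi D t)^(-3/2) exp(-R^2/(4 D t))``.

    Probability density per unit volume (1/m^3) of finding a molecule at
    distance R from its origin after time t. Normalizes to 1 over all
    space; second radial moment is ``<R^2> = 6 D t``.
    """
    _check_positive(D=D, t=t)
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("radius must be >= 0")
    out = (4.0 * math.pi * D * t) ** -1.5 * np.exp(-(R**2) / (4.0 * D * t))
    return float(out) if out.ndim == 0 else out


def propagator_radial_pdf(R, D: float, t: float):
    """Radial density ``4 pi R^2 * propagator_pdf`` (1/m); peaks at
    ``R* = 2 sqrt(D t)``."""
    R = np.asarray(R, dtype=float)
    out = 4.0 * math.pi * R**2 * propagator_pdf(R, D, t)
    return float(out) if out.ndim == 0 else out


def first_passage_prob_1d(L: float, D: float, t):
    """Probability a 1D Brownian walker from the origin has reached the
    level ``L`` by time ``t``: ``erfc(L / sqrt(4 D t))`` (reflection
    principle). Closed-form oracle for the random-walk simulator."""
    _check_positive(L=L, D=D, t=t)
    out = erfc(L / np.sqrt(4.0 * D * np.asarray(t, dtype=float)))
    return float(out) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class CollisionQuery:
    """Inputs to hard-sphere collision frequency: cross section (m^2),
    reduced mass (kg), temperature (K), partner concentration (1/m^3)."""

    cross_section: float
    reduced_mass: float
    temperature: float
    partner_concentration: float

    def __post_init__(self) -> None:
        _check_positive(
            cross_section=self.cross_section,
            reduced_mass=self.reduced_mass,
            temperature=self.temperature,
            partner_concentration=self.partner_concentration,
        )

    def frequency(self) -> float:
        return collision_frequency_hard_sphere(self)


def mean_thermal_speed(reduced_mass: float, temperature: float) -> float:
    """Maxwell-Boltzmann mean relative speed ``sqrt(8 k_B T / (pi m))`` (m/s)."""
    _check_positive(reduced_mass=reduced_mass, temperature=temperature)
    return math.sqrt(8.0 * BOLTZMANN * temperature / (math.pi * reduced_mass))


def collision_frequency_hard_sphere(query: CollisionQuery) -> float:
    """Hard-sphere collision frequency ``sigma * C_B * <v>`` (1/s).

    Closed form of the Maxwell-Boltzmann speed integral over the virtual
    swept volume ``sigma v t``, divided by t. The gas-kinetic benchmark
    that the diffusive models are contrasted against: linear in both time
    and concentration.
    """
    return (
        query.cross_section
        * query.partner_concentration
        * mean_thermal_speed(query.reduced_mass, query.temperature)
    )
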