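"""Core record types and concentration conversions.

Everything downstream — transport closed forms, the rate-equation family,
fitting, and the Brownian-dynamics simulator — consumes these types.
Quantities are stored in SI units; number concentration is in 1/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .constants import AVOGADRO

__all__ = [
    "SpeciesSpec",
    "SolutionConditions",
    "RateMeasurement",
    "RateDataset",
    "molar_to_number_density",
    "number_density_to_molar",
    "nanomolar_to_number_density",
    "number_density_to_nanomolar",
]


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative number, got {value!r}")


# ---------------------------------------------------------------------------
# concentration conversions
# ---------------------------------------------------------------------------

def molar_to_number_density(c):
    """Convert molar concentration (mol/L) to number density (1/m^3).

    ``C = c * 1000 * N_A``; exact linear map. Accepts scalars or arrays;
    negative or non-finite input raises :class:`ValueError`.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("molar concentration must be finite and non-negative")
    out = arr * 1000.0 * AVOGADRO
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def number_density_to_molar(C):
    """Convert number density (1/m^3) back to molar concentration (mol/L).

    Exact inverse of :func:`molar_to_number_density`.
    """
    arr = np.asarray(C, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("number density must be finite and non-negative")
    out = arr / (1000.0 * AVOGADRO)
    return float(out) if np.isscalar(C) or arr.ndim == 0 else out


def nanomolar_to_number_density(c_nM):
    """Convert nM to number density in 1/m^3 (1 nM -> 6.022e17 /m^3)."""
    arr = np.asarray(c_nM, dtype=float)
    out = molar_to_number_density(arr * 1e-9)
    return out


def number_density_to_nanomolar(C):
    """Convert number density in 1/m^3 to nM."""
    arr = np.asarray(C, dtype=float)
    out = number_density_to_molar(arr)
    out = out * 1e9
    return float(out) if np.isscalar(C) or np.asarray(C).ndim == 0 else out


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """Size/transport descriptors of one molecular species.

    At least one of ``radius``, the pair ``(molecular_weight, density)``,
    or ``diffusion_coefficient`` must be given; the missing descriptors
    are resolved lazily (radius from Mw and density via the compact-sphere
    relation, D from the radius via Stokes-Einstein).

    Parameters
    ----------
    name : str
    molecular_weight : float, optional
        kg/mol.
    density : float, optional
        kg/m^3 (neat solid/liquid density of the molecule).
    radius : float, optional
        Hydrodynamic radius, m.
    diffusion_coefficient : float, optional
        m^2/s.
    """

    name: str
    molecular_weight: Optional[float] = None
    density: Optional[float] = None
    radius: Optional[float] = None
    diffusion_coefficient: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("molecular_weight", "density", "radius", "diffusion_coefficient"):
            value = getattr(self, attr)
            if value is not None:
                _require_positive(attr, value)
        has_mw_pair = self.molecular_weight is not None and self.density is not None
        if self.radius is None and not has_mw_pair and self.diffusion_coefficient is None:
            raise ValueError(
                "SpeciesSpec needs radius, (molecular_weight, density), "
                "or diffusion_coefficient"
            )

    def resolved_radius(self) -> float:
        """Radius in m; derived from Mw and density when not stored."""
        if self.radius is not None:
            return self.radius
        if self.molecular_weight is not None and self.density is not None:
            from .transport import radius_from_molweight

            return radius_from_molweight(self.molecular_weight, self.density)
        raise ValueError(f"cannot resolve radius for species {self.name!r}")

    def resolved_diffusion(self, conditions: "SolutionConditions") -> float:
        """Diffusion coefficient in m^2/s; Stokes-Einstein when not stored."""
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        from .transport import stokes_einstein_D

        return stokes_einstein_D(
            conditions.temperature, conditions.viscosity, self.resolved_radius()
        )


@dataclass(frozen=True)
class SolutionConditions:
    """Bulk solution state: temperature (K), viscosity (Pa s), number
    concentration (1/m^3)."""

    temperature: float
    viscosity: float
    number_concentration: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("temperature", self.temperature)
        _require_positive("viscosity", self.viscosity)
        _require_nonnegative("number_concentration", self.number_concentration)


@dataclass(frozen=True)
class RateMeasurement:
    """One measured point: probe number concentration (1/m^3) and the
    per-target association rate (1/s)."""

    concentration: float
    rate: float

    def __post_init__(self) -> None:
        _require_positive("concentration", self.concentration)
        _require_nonnegative("rate", self.rate)


@dataclass(frozen=True)
class RateDataset:
    """Ordered rate-vs-concentration measurements for one probe/target pair.

    Concentrations must be strictly increasing; use :meth:`from_arrays`
    to build from plain sequences (it sorts first).
    """

    measurements: tuple
    probe: Optional[SpeciesSpec] = None
    label: str = ""

    def __post_init__(self) -> None:
        ms = tuple(self.measurements)
        object.__setattr__(self, "measurements", ms)
        if len(ms) < 1:
            raise ValueError("RateDataset needs at least one measurement")
        conc = [m.concentration for m in ms]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")

    @classmethod
    def from_arrays(
        cls,
        concentrations: Iterable[float],
        rates: Iterable[float],
        probe: Optional[SpeciesSpec] = None,
        label: str = "",
    ) -> "RateDataset":
        pairs = sorted(zip(concentrations, rates), key=lambda p: p[0])
        ms = tuple(RateMeasurement(c, r) for c, r in pairs)
        return cls(measurements=ms, probe=probe, label=label)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def concentrations(self) -> np.ndarray:
        """Number concentrations, 1/m^3."""
        return np.array([m.concentration for m in self.measurements])

    @property
    def rates(self) -> np.ndarray:
        """Measured per-target rates, 1/s."""
        return np.array([m.rate for m in self.measurements])

    def to_dataframe(self):
        """Bench-unit view (``conc_nM``, ``rate_per_s``) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "conc_nM": number_density_to_nanomolar(self.concentrations),
                "rate_per_s": self.rates,
            }
        )
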