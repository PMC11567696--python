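"""The diffusive association rate-equation family.

Seven models for the per-target association rate r (1/s) of diffusing
probes at number concentration C (1/m^3) with relative diffusion
coefficient D (m^2/s):

======================  ============================================  =========
model                   rate law                                      order in C
======================  ============================================  =========
naive_continuous        r = C V0 / t                                  1
discrete_0d             r = 2 a / t_c            = 4 a D C^(2/3)      2/3
smoluchowski_1d         r = 4 pi r0 C D                               1
discrete_2d             r = (4/pi) A D C^(4/3)                        4/3
discrete_2d_tc          r = 2 sqrt(2/pi) A D C^(4/3)                  4/3
langmuir_schaefer       r = 2 A C sqrt(D / (pi t))                    1
discrete_3d             r = 2 C V0 / t_c         = 4 V0 D C^(5/3)     5/3
======================  ============================================  =========

The discrete models count one nearest-neighbour encounter attempt per
critical reshuffle time ``t_c = 1/(2 D C^(2/3))`` weighted by an
effective geometric fraction, times an empirical factor 2 for the
fractal (self-similar) sub-steps of diffusion; the Smoluchowski and
Langmuir-Schaefer models instead assume a continuously evolving Fick
gradient. Each model carries a single geometry parameter (a, r0, A or
V0), so a measured rate inverts uniquely to that parameter.

The 2D model's coefficient is 4/pi, fixed by substituting the area
fraction a = 4A/(4 pi L^2) into the 0D law; the 2D-at-t_c variant's
coefficient 2 sqrt(2/pi) follows from evaluating the Langmuir-Schaefer
law at t = t_c. Fractional powers are taken on positive reals only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional

import numpy as np

from .constants import GAS_CONSTANT, STANDARD_CONCENTRATION
from .transport import critical_time, mean_separation

__all__ = [
    "ModelId",
    "GeometryParams",
    "DimensionalSignature",
    "rate_naive",
    "rate_0d",
    "rate_2d",
    "rate_2d_tc",
    "rate_langmuir_schaefer",
    "rate_smoluchowski",
    "rate_3d",
    "rate_3d_area_form",
    "effective_fraction_from_area",
    "effective_fraction_from_volume",
    "invert_model",
    "invert_langmuir_schaefer",
    "cylinder_radius_from_area",
    "cylinder_radius_from_volume",
    "dimensional_signature",
    "predict_rate",
    "registry_to_json",
    "arrhenius_pseudo_first_order",
    "equilibrium_constant_from_free_energy",
    "dissociation_constant",
    "TIME_INDEPENDENT_MODELS",
    "INVERTIBLE_MODELS",
]


class ModelId(str, Enum):
    """Closed enumeration of the rate models."""

    NAIVE_CONTINUOUS = "naive_continuous"
    DISCRETE_0D = "discrete_0d"
    SMOLUCHOWSKI_1D = "smoluchowski_1d"
    DISCRETE_2D = "discrete_2d"
    DISCRETE_2D_TC = "discrete_2d_tc"
    LANGMUIR_SCHAEFER = "langmuir_schaefer"
    DISCRETE_3D = "discrete_3d"


#: Models whose rate law does not depend on elapsed time.
TIME_INDEPENDENT_MODELS = (
    ModelId.DISCRETE_0D,
    ModelId.SMOLUCHOWSKI_1D,
    ModelId.DISCRETE_2D,
    ModelId.DISCRETE_2D_TC,
    ModelId.DISCRETE_3D,
)

#: Models invertible for their geometry parameter from (r, C, D) alone.
INVERTIBLE_MODELS = TIME_INDEPENDENT_MODELS


def _pos(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class GeometryParams:
    """Per-model effective collision geometry.

    Only the field the chosen model uses needs to be set: effective
    fraction a (0D, dimensionless), collision radius r0 (1D, m),
    collision area A (2D, m^2), collision volume V0 (3D, m^3). The
    cylinder length (m, default 1 um, the stretched-DNA target length)
    converts areas/volumes to equivalent cylinder radii.
    """

    effective_fraction_a: Optional[float] = None
    collision_radius_r0: Optional[float] = None
    collision_area_A: Optional[float] = None
    collision_volume_V0: Optional[float] = None
    cylinder_length: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in (
            "effective_fraction_a",
            "collision_radius_r0",
            "collision_area_A",
            "collision_volume_V0",
        ):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.effective_fraction_a is not None and self.effective_fraction_a > 1:
            raise ValueError("effective_fraction_a must be <= 1")
        _pos("cylinder_length", self.cylinder_length)

    def parameter_for(self, model: ModelId) -> float:
        """The single geometry parameter the given model consumes."""
        name = _GEOMETRY_FIELD[model]
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"model {model.value} requires {name}")
        return value


_GEOMETRY_FIELD = {
    ModelId.NAIVE_CONTINUOUS: "collision_volume_V0",
    ModelId.DISCRETE_0D: "effective_fraction_a",
    ModelId.SMOLUCHOWSKI_1D: "collision_radius_r0",
    ModelId.DISCRETE_2D: "collision_area_A",
    ModelId.DISCRETE_2D_TC: "collision_area_A",
    ModelId.LANGMUIR_SCHAEFER: "collision_area_A",
    ModelId.DISCRETE_3D: "collision_volume_V0",
}


# ---------------------------------------------------------------------------
# forward rate laws
# ---------------------------------------------------------------------------

def rate_naive(C, V0: float, t: float):
    """Naive continuous overlap rate ``r = C V0 / t`` (1/s).

    Dimensionally correct but physically confusing: it decays as 1/t and
    is independent of D. Kept as the family's cautionary baseline.
    """
    _pos("C", C), _pos("V0", V0), _pos("t", t)
    out = np.asarray(C, dtype=float) * V0 / t
    return float(out) if np.ndim(C) == 0 else out


def rate_0d(a: float, D: float, C):
    """Discrete 0D rate ``r = 2 a / t_c = 4 a D C^(2/3)`` (1/s).

    One nearest-neighbour attempt per reshuffle time, a fraction ``a`` of
    which hit, times the fractal factor 2. ``a`` may be 0 (no capture).
    """
    if not (0 <= a <= 1):
        raise ValueError(f"effective fraction a must be in [0, 1], got {a!r}")
    _pos("D", D), _pos("C", C)
    out = 4.0 * a * D * np.asarray(C, dtype=float) ** (2.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


def effective_fraction_from_area(A: float, L: float) -> float:
    """Area-ratio effective fraction ``a = 4A / (4 pi L^2) = A / (pi L^2)``.

    Four probes in the first neighbour shell (cubic/tetrahedral packing),
    each presenting binding cross-section A on the shell of radius L.
    Raises if the geometry exceeds the neighbour sphere (a > 1).
    """
    _pos("A", A), _pos("L", L)
    a = A / (math.pi * L**2)
    if a > 1:
        raise ValueError("binding area exceeds the first-neighbour sphere (a > 1)")
    return a


def rate_2d(A: float, D: float, C):
    """Discrete 2D rate ``r = (4/pi) A D C^(4/3)`` (1/s).

    The area fraction of the first-neighbour sphere substituted into the
    0D law; identical to composing :func:`effective_fraction_from_area`
    with :func:`rate_0d` at ``L = C^(-1/3)``.
    """
    _pos("A", A), _pos("D", D), _pos("C", C)
    out = (4.0 / math.pi) * A * D * np.asarray(C, dtype=float) ** (4.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


def rate_langmuir_schaefer(A: float, C, D: float, t: float):
    """Langmuir-Schaefer transient adsorption rate ``r = 2 A C sqrt(D/(pi t))``.

    Continuous Fick-gradient flux onto an absorbing interface; decays as
    1/sqrt(t) as the sub-surface layer depletes.
    """
    _pos("A", A), _pos("C", C), _pos("D", D), _pos("t", t)
    out = 2.0 * A * np.asarray(C, dtype=float) * math.sqrt(D / (math.pi * t))
    return float(out) if np.ndim(C) == 0 else out


def rate_2d_tc(A: float, D: float, C):
    """Langmuir-Schaefer evaluated at the reshuffle time:
    ``r = 2 sqrt(2/pi) A D C^(4/3)`` (1/s).

    Same C and D scaling as the discrete 2D law; the coefficient ratio to
    :func:`rate_2d` is the constant ``sqrt(pi/2) ~ 1.2533``.
    """
    _pos("A", A), _pos("D", D), _pos("C", C)
    out = 2.0 * math.sqrt(2.0 / math.pi) * A * D * np.asarray(C, dtype=float) ** (4.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


def rate_smoluchowski(r0: float, C, D: float):
    """Smoluchowski steady-state diffusive flux ``r = 4 pi r0 C D`` (1/s).

    The classical diffusion-controlled benchmark; first order in C.
    """
    _pos("r0", r0), _pos("C", C), _pos("D", D)
    out = 4.0 * math.pi * r0 * np.asarray(C, dtype=float) * D
    return float(out) if np.ndim(C) == 0 else out


def effective_fraction_from_volume(C: float, V0: float) -> float:
    """Volume-ratio effective fraction ``a = C V0`` (probe collision volume
    per unit solution volume). Raises when C V0 > 1 (overlapping volumes)."""
    _pos("C", C), _pos("V0", V0)
    a = C * V0
    if a > 1:
        raise ValueError("collision volume exceeds the per-molecule volume (a > 1)")
    return a


def rate_3d(V0: float, D: float, C):
    """Discrete 3D rate ``r = 2 C V0 / t_c = 4 V0 D C^(5/3)`` (1/s).

    Volume-fraction form of the 0D law; assumes probe and target can pass
    through each other so only volume overlap counts.
    """
    _pos("V0", V0), _pos("D", D), _pos("C", C)
    out = 4.0 * V0 * D * np.asarray(C, dtype=float) ** (5.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


def rate_3d_area_form(r0: float, L: float, D: float, C):
    """Discrete 3D rate rewritten through the collision radius:
    ``r = (16 pi / 3) (r0^3 / L) D C^(4/3)``.

    Algebraic rewrite of :func:`rate_3d` with a spherical collision
    volume ``V0 = (4/3) pi r0^3`` and ``C^(1/3) = 1/L``; smaller than the
    2D law by a factor of order r0/L.
    """
    _pos("r0", r0), _pos("L", L), _pos("D", D), _pos("C", C)
    if r0 >= L:
        raise ValueError("collision radius must be smaller than the mean separation")
    out = (16.0 * math.pi / 3.0) * (r0**3 / L) * D * np.asarray(C, dtype=float) ** (4.0 / 3.0)
    return float(out) if np.ndim(C) == 0 else out


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def invert_model(model: ModelId, r: float, C: float, D: float) -> GeometryParams:
    """Solve a time-independent model for its geometry parameter.

    Given a measured per-target rate r (1/s) at concentration C (1/m^3)
    with relative diffusion D (m^2/s), returns a :class:`GeometryParams`
    with the single inverted field set:

    * discrete_0d:      a  = r / (4 D C^(2/3))
    * smoluchowski_1d:  r0 = r / (4 pi C D)
    * discrete_2d:      A  = r pi / (4 D C^(4/3))
    * discrete_2d_tc:   A  = r / (2 sqrt(2/pi) D C^(4/3))
    * discrete_3d:      V0 = r / (4 D C^(5/3))

    The time-dependent models need an explicit time (see
    :func:`invert_langmuir_schaefer`).
    """
    model = ModelId(model)
    if r < 0 or not math.isfinite(r):
        raise ValueError("rate must be finite and >= 0")
    _pos("C", C), _pos("D", D)
    if model == ModelId.DISCRETE_0D:
        return GeometryParams(effective_fraction_a=r / (4.0 * D * C ** (2.0 / 3.0)))
    if model == ModelId.SMOLUCHOWSKI_1D:
        return GeometryParams(collision_radius_r0=r / (4.0 * math.pi * C * D))
    if model == ModelId.DISCRETE_2D:
        return GeometryParams(collision_area_A=r * math.pi / (4.0 * D * C ** (4.0 / 3.0)))
    if model == ModelId.DISCRETE_2D_TC:
        return GeometryParams(
            collision_area_A=r / (2.0 * math.sqrt(2.0 / math.pi) * D * C ** (4.0 / 3.0))
        )
    if model == ModelId.DISCRETE_3D:
        return GeometryParams(collision_volume_V0=r / (4.0 * D * C ** (5.0 / 3.0)))
    raise LookupError(
        f"model {model.value} is not invertible from (r, C, D) alone; "
        "use invert_langmuir_schaefer for time-dependent models"
    )


def invert_langmuir_schaefer(r: float, C: float, D: float, t: float) -> GeometryParams:
    """Solve the Langmuir-Schaefer law for A at an explicit elapsed time."""
    if r < 0 or not math.isfinite(r):
        raise ValueError("rate must be finite and >= 0")
    _pos("C", C), _pos("D", D), _pos("t", t)
    return GeometryParams(collision_area_A=r / (2.0 * C * math.sqrt(D / (math.pi * t))))


def cylinder_radius_from_area(A: float, ell: float) -> float:
    """Equivalent cylinder radius from a rectangular footprint: ``r0 = A / ell``.

    Convention used to convert the 2D model's collision area on a
    cylinder of length ell (the stretched DNA target) to a radius.
    """
    _pos("A", A), _pos("ell", ell)
    return A / ell


def cylinder_radius_from_volume(V0: float, ell: float) -> float:
    """Equivalent cylinder radius from a square-cross-section prism:
    ``r0 = sqrt(V0 / ell)``."""
    _pos("V0", V0), _pos("ell", ell)
    return math.sqrt(V0 / ell)


# ---------------------------------------------------------------------------
# dispatch + dimensional bookkeeping
# ---------------------------------------------------------------------------

def predict_rate(
    model: ModelId,
    geometry: GeometryParams,
    D: float,
    C,
    t: Optional[float] = None,
):
    """Forward rate for any model; time-dependent models require ``t``."""
    model = ModelId(model)
    param = geometry.parameter_for(model)
    if model == ModelId.NAIVE_CONTINUOUS:
        if t is None:
            raise ValueError("naive_continuous requires an elapsed time t")
        return rate_naive(C, param, t)
    if model == ModelId.DISCRETE_0D:
        return rate_0d(param, D, C)
    if model == ModelId.SMOLUCHOWSKI_1D:
        return rate_smoluchowski(param, C, D)
    if model == ModelId.DISCRETE_2D:
        return rate_2d(param, D, C)
    if model == ModelId.DISCRETE_2D_TC:
        return rate_2d_tc(param, D, C)
    if model == ModelId.LANGMUIR_SCHAEFER:
        if t is None:
            raise ValueError("langmuir_schaefer requires an elapsed time t")
        return rate_langmuir_schaefer(param, C, D, t)
    if model == ModelId.DISCRETE_3D:
        return rate_3d(param, D, C)
    raise LookupError(f"unknown model {model!r}")


@dataclass(frozen=True)
class DimensionalSignature:
    """Unit/exponent signature of one rate law.

    ``rate = coefficient * geometry * D^diffusion_exponent *
    C^concentration_exponent * t^time_exponent`` must carry SI units of
    1/s; :meth:`si_unit_exponents` performs that audit symbolically.
    """

    model: ModelId
    concentration_exponent: Fraction
    diffusion_exponent: Fraction
    geometry_symbol: str  # one of a, r0, A, V0
    time_dependent: bool
    coefficient: float
    time_exponent: Fraction = Fraction(0)

    _GEOMETRY_LENGTH_EXPONENT = {"a": 0, "r0": 1, "A": 2, "V0": 3}

    def si_unit_exponents(self) -> tuple:
        """(metre exponent, second exponent) of the full rate expression."""
        m = (
            -3 * self.concentration_exponent
            + 2 * self.diffusion_exponent
            + self._GEOMETRY_LENGTH_EXPONENT[self.geometry_symbol]
        )
        s = -self.diffusion_exponent + self.time_exponent
        return (Fraction(m), Fraction(s))


_REGISTRY = {
    ModelId.NAIVE_CONTINUOUS: DimensionalSignature(
        ModelId.NAIVE_CONTINUOUS, Fraction(1), Fraction(0), "V0", True, 1.0, Fraction(-1)
    ),
    ModelId.DISCRETE_0D: DimensionalSignature(
        ModelId.DISCRETE_0D, Fraction(2, 3), Fraction(1), "a", False, 4.0
    ),
    ModelId.SMOLUCHOWSKI_1D: DimensionalSignature(
        ModelId.SMOLUCHOWSKI_1D, Fraction(1), Fraction(1), "r0", False, 4.0 * math.pi
    ),
    ModelId.DISCRETE_2D: DimensionalSignature(
        ModelId.DISCRETE_2D, Fraction(4, 3), Fraction(1), "A", False, 4.0 / math.pi
    ),
    ModelId.DISCRETE_2D_TC: DimensionalSignature(
        ModelId.DISCRETE_2D_TC,
        Fraction(4, 3),
        Fraction(1),
        "A",
        False,
        2.0 * math.sqrt(2.0 / math.pi),
    ),
    ModelId.LANGMUIR_SCHAEFER: DimensionalSignature(
        ModelId.LANGMUIR_SCHAEFER,
        Fraction(1),
        Fraction(1, 2),
        "A",
        True,
        2.0 / math.sqrt(math.pi),
        Fraction(-1, 2),
    ),
    ModelId.DISCRETE_3D: DimensionalSignature(
        ModelId.DISCRETE_3D, Fraction(5, 3), Fraction(1), "V0", False, 4.0
    ),
}


def dimensional_signature(model: ModelId) -> DimensionalSignature:
    """Registry lookup of a model's exponent/unit signature."""
    return _REGISTRY[ModelId(model)]


def registry_to_json() -> list:
    """JSON-serializable dump of the model registry (for the CLI)."""
    return [
        {
            "model": sig.model.value,
            "coefficient": sig.coefficient,
            "concentration_exponent": str(sig.concentration_exponent),
            "diffusion_exponent": str(sig.diffusion_exponent),
            "time_exponent": str(sig.time_exponent),
            "geometry_symbol": sig.geometry_symbol,
            "time_dependent": sig.time_dependent,
        }
        for sig in _REGISTRY.values()
    ]


# ---------------------------------------------------------------------------
# thermodynamic utilities
# ---------------------------------------------------------------------------

def arrhenius_pseudo_first_order(F_BA: float, Ea: float, T: float) -> float:
    """Arrhenius pseudo-first-order rate ``F_BA exp(-Ea / (R T))`` (1/s).

    F_BA is the collision-attempt frequency; Ea in J/mol. Barrierless
    (Ea = 0) returns F_BA.
    """
    if F_BA < 0:
        raise ValueError("attempt frequency must be >= 0")
    _pos("T", T)
    return F_BA * math.exp(-Ea / (GAS_CONSTANT * T))


def equilibrium_constant_from_free_energy(
    dG: float, T: float, C_ref: float = STANDARD_CONCENTRATION
) -> float:
    """Association constant from reaction free energy (J/mol):
    ``Ka = exp(-dG / (R T)) / C_ref``, returned in L/mol.

    ``C_ref`` is the standard concentration in mol/m^3 (default 1 mol/L
    = 1000 mol/m^3); dG = 0 gives Ka = 1 L/mol.
    """
    _pos("T", T), _pos("C_ref", C_ref)
    ka_m3_per_mol = math.exp(-dG / (GAS_CONSTANT * T)) / C_ref
    return ka_m3_per_mol * 1000.0


def dissociation_constant(Ka: float) -> float:
    """``Kd = 1 / Ka`` (mol/L when Ka is in L/mol)."""
    _pos("Ka", Ka)
    return 1.0 / Ka
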