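"""Embedded reference dataset: YOYO-1 binding to surface-stretched λ-DNA.

Single-molecule fluorescence measurements of the initial per-target
binding rate of the bis-intercalating dye YOYO-1 to individual 1 µm
flow-stretched λ-DNA segments immobilized on glass, at six probe
concentrations. Stored verbatim as published (bench units), together
with the published derived model parameters used for regression testing.

The published reshuffle-time column is kept for completeness but is
known to disagree by a factor of ~10 with ``t_c = 1/(2 D C^(2/3))``
evaluated at the published D; see ``PRINTED_TC_US`` and the methods
note. It is excluded from pass/fail comparisons.
"""

from __future__ import annotations

import hashlib
import json

from .core import RateDataset, SpeciesSpec, nanomolar_to_number_density
from .models import GeometryParams

__all__ = [
    "yoyo1_probe",
    "dna_target_geometry",
    "binding_rate_dataset",
    "PRINTED_CONC_NM",
    "PRINTED_RATES_PER_S",
    "PRINTED_DERIVED",
    "PRINTED_TC_US",
    "PROBE_DIFFUSION_M2_S",
    "CYLINDER_LENGTH_M",
    "fixture_checksum",
    "FROZEN_FIXTURE_SHA256",
]

#: Published probe diffusion coefficient, m^2/s.
PROBE_DIFFUSION_M2_S = 2.9e-10

#: Length of the stretched DNA target, m.
CYLINDER_LENGTH_M = 1.0e-6

#: Probe concentrations, nM (as published).
PRINTED_CONC_NM = (1.0, 3.0, 5.0, 10.0, 50.0, 100.0)

#: Measured per-target binding rates, 1/s (as published).
PRINTED_RATES_PER_S = (0.63, 1.49, 2.85, 4.0, 10.0, 15.0)

#: Published derived model parameters per concentration row, bench units:
#: mean separation L (µm); 0D effective fraction a (×10⁻³); Smoluchowski
#: radius r0 (nm); 2D collision area A (nm²) and its cylinder radius (nm);
#: 3D collision volume V (×10⁴ nm³) and its cylinder radius (nm).
PRINTED_DERIVED = {
    "L_um": (1.2, 0.8, 0.7, 0.55, 0.32, 0.25),
    "a_e3": (0.77, 0.87, 1.2, 1.1, 0.90, 0.85),
    "r0_1d_nm": (0.29, 0.23, 0.26, 0.18, 0.09, 0.07),
    "A_nm2": (3400.0, 1900.0, 1800.0, 1000.0, 290.0, 170.0),
    "r0_2d_nm": (3.4, 1.9, 1.8, 1.0, 0.29, 0.17),
    "V_e4nm3": (130.0, 49.0, 40.0, 18.0, 3.0, 1.4),
    "r0_3d_nm": (36.0, 22.0, 20.0, 13.0, 5.5, 3.8),
}

#: Published reshuffle-time column, µs — known ×10 inconsistency with
#: t_c = 1/(2 D C^(2/3)) at the published D; not used in comparisons.
PRINTED_TC_US = (240.0, 120.0, 83.0, 53.0, 18.0, 11.0)


def yoyo1_probe() -> SpeciesSpec:
    """The YOYO-1 probe as published: Mw 1271 g/mol, radius ~0.9 nm,
    D = 2.9e-10 m^2/s.

    Radius and D are both stored verbatim rather than deriving one from
    the other (they are mutually Stokes-Einstein-consistent only for a
    viscosity of ~0.84 mPa s at 298 K, and the measurement conditions
    were not published).
    """
    return SpeciesSpec(
        name="YOYO-1",
        molecular_weight=1.271,  # kg/mol
        radius=0.9e-9,
        diffusion_coefficient=PROBE_DIFFUSION_M2_S,
    )


def dna_target_geometry() -> GeometryParams:
    """Published order-of-magnitude geometry of the stretched λ-DNA target:
    cylinder radius ~1 nm, area ~2000 nm², volume ~3000 nm³, length 1 µm."""
    return GeometryParams(
        collision_radius_r0=1.0e-9,
        collision_area_A=2000e-18,
        collision_volume_V0=3000e-27,
        cylinder_length=CYLINDER_LENGTH_M,
    )


def binding_rate_dataset() -> RateDataset:
    """The six published (concentration, rate) measurements as a
    :class:`~diffrate.core.RateDataset` (SI units)."""
    conc = [float(nanomolar_to_number_density(c)) for c in PRINTED_CONC_NM]
    return RateDataset.from_arrays(
        conc, PRINTED_RATES_PER_S, probe=yoyo1_probe(), label="YOYO-1 / lambda-DNA"
    )


#: SHA-256 of the canonical JSON dump of every frozen published value;
#: a regression test fails if any printed value is edited.
FROZEN_FIXTURE_SHA256 = "eb4b04da48daef6b9aab3fe2745544abbce4a7eed1064ef15be49a43902e79e4"


def fixture_checksum() -> str:
    """Checksum of the frozen published values (guards against edits)."""
    payload = {
        "D": PROBE_DIFFUSION_M2_S,
        "ell": CYLINDER_LENGTH_M,
        "conc_nM": PRINTED_CONC_NM,
        "rates": PRINTED_RATES_PER_S,
        "derived": PRINTED_DERIVED,
        "tc_us": PRINTED_TC_US,
    }
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(text.encode()).hexdigest()
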