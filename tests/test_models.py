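"""Rate-equation family: forward values, algebraic identities, inversion,
dimensional bookkeeping, thermodynamic utilities."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from diffrate.constants import GAS_CONSTANT
from diffrate.core import nanomolar_to_number_density
from diffrate.models import (
    INVERTIBLE_MODELS,
    GeometryParams,
    ModelId,
    arrhenius_pseudo_first_order,
    cylinder_radius_from_area,
    cylinder_radius_from_volume,
    dimensional_signature,
    dissociation_constant,
    effective_fraction_from_area,
    effective_fraction_from_volume,
    equilibrium_constant_from_free_energy,
    invert_langmuir_schaefer,
    invert_model,
    predict_rate,
    rate_0d,
    rate_2d,
    rate_2d_tc,
    rate_3d,
    rate_3d_area_form,
    rate_langmuir_schaefer,
    rate_naive,
    rate_smoluchowski,
    registry_to_json,
)
from diffrate.transport import critical_time, mean_separation

D_REF = 2.9e-10

pos_D = st.floats(min_value=1e-12, max_value=1e-8)
pos_C = st.floats(min_value=1e15, max_value=1e24)
pos_A = st.floats(min_value=1e-20, max_value=1e-15)
pos_r0 = st.floats(min_value=1e-11, max_value=1e-8)
pos_V0 = st.floats(min_value=1e-28, max_value=1e-22)


class TestForwardValuesAgainstPublishedTable:
    """Spot checks against published model-parameter cells (±10%,
    printed values are 2-significant-figure roundings)."""

    def test_rate_0d_at_3nM(self):
        C = nanomolar_to_number_density(3.0)
        assert rate_0d(0.87e-3, D_REF, C) == pytest.approx(1.49, rel=0.10)

    def test_rate_2d_at_1nM(self):
        C = nanomolar_to_number_density(1.0)
        assert rate_2d(3.4e-15, D_REF, C) == pytest.approx(0.63, rel=0.10)

    def test_smoluchowski_at_1nM_and_100nM(self):
        assert rate_smoluchowski(
            0.29e-9, nanomolar_to_number_density(1.0), D_REF
        ) == pytest.approx(0.63, rel=0.10)
        assert rate_smoluchowski(
            0.07e-9, nanomolar_to_number_density(100.0), D_REF
        ) == pytest.approx(15.0, rel=0.10)

    def test_rate_3d_at_100nM(self):
        C = nanomolar_to_number_density(100.0)
        assert rate_3d(1.4e-23, D_REF, C) == pytest.approx(15.0, rel=0.10)

    def test_langmuir_schaefer_value(self):
        C = nanomolar_to_number_density(1.0)
        assert rate_langmuir_schaefer(3.4e-15, C, D_REF, 1.0) == pytest.approx(
            3.93e-2, rel=1e-2
        )

    def test_rate_naive_value(self):
        assert rate_naive(6.022e17, 1e-27, 1.0) == pytest.approx(6.022e-10, rel=1e-6)


class TestScalingLaws:
    def test_power_law_exponents_numerically(self):
        """Log-log slope of each model equals its registry exponent."""
        geometry = GeometryParams(
            effective_fraction_a=1e-3,
            collision_radius_r0=1e-9,
            collision_area_A=1e-17,
            collision_volume_V0=1e-25,
        )
        C1, C2 = 1e18, 1e20
        for model in ModelId:
            sig = dimensional_signature(model)
            t = 1.0 if sig.time_dependent else None
            r1 = predict_rate(model, geometry, D_REF, C1, t=t)
            r2 = predict_rate(model, geometry, D_REF, C2, t=t)
            slope = math.log(r2 / r1) / math.log(C2 / C1)
            assert slope == pytest.approx(float(sig.concentration_exponent), abs=1e-9)

    def test_simple_scalings(self):
        C = 1e18
        assert rate_0d(1e-3, D_REF, 8 * C) == pytest.approx(
            4 * rate_0d(1e-3, D_REF, C), rel=1e-12
        )
        assert rate_2d(1e-17, D_REF, 8 * C) == pytest.approx(
            16 * rate_2d(1e-17, D_REF, C), rel=1e-12
        )
        assert rate_3d(1e-25, D_REF, 8 * C) == pytest.approx(
            32 * rate_3d(1e-25, D_REF, C), rel=1e-12
        )
        assert rate_smoluchowski(1e-9, 2 * C, D_REF) == pytest.approx(
            2 * rate_smoluchowski(1e-9, C, D_REF), rel=1e-12
        )
        assert rate_naive(C, 1e-25, 2.0) == pytest.approx(
            rate_naive(C, 1e-25, 1.0) / 2, rel=1e-12
        )
        assert rate_langmuir_schaefer(1e-17, C, D_REF, 4.0) == pytest.approx(
            rate_langmuir_schaefer(1e-17, C, D_REF, 1.0) / 2, rel=1e-12
        )

    @given(pos_D, pos_C)
    def test_monotonicity_in_C_and_D(self, D, C):
        geometry = GeometryParams(
            effective_fraction_a=1e-3,
            collision_radius_r0=1e-10,
            collision_area_A=1e-18,
            collision_volume_V0=1e-27,
        )
        for model in INVERTIBLE_MODELS:
            r = predict_rate(model, geometry, D, C)
            assert predict_rate(model, geometry, D, C * 1.5) > r
            assert predict_rate(model, geometry, D * 1.5, C) > r


class TestAlgebraicIdentities:
    @given(pos_A, pos_D, pos_C)
    def test_2d_is_area_fraction_composed_with_0d(self, A, D, C):
        L = mean_separation(C)
        a = A / (math.pi * L**2)
        if a > 1:
            return
        assert rate_2d(A, D, C) == pytest.approx(rate_0d(a, D, C), rel=1e-12)

    @given(pos_V0, pos_D, pos_C)
    def test_3d_is_volume_fraction_composed_with_0d(self, V0, D, C):
        a = C * V0
        if a > 1:
            return
        assert rate_3d(V0, D, C) == pytest.approx(rate_0d(a, D, C), rel=1e-12)

    @given(pos_A, pos_D, pos_C)
    def test_2d_tc_is_langmuir_schaefer_at_critical_time(self, A, D, C):
        tc = critical_time(D, C)
        assert rate_2d_tc(A, D, C) == pytest.approx(
            rate_langmuir_schaefer(A, C, D, tc), rel=1e-12
        )

    @given(pos_r0, pos_D, pos_C)
    def test_3d_area_form_is_rewrite_of_3d(self, r0, D, C):
        L = mean_separation(C)
        if r0 >= L:
            return
        V0 = (4.0 / 3.0) * math.pi * r0**3
        assert rate_3d_area_form(r0, L, D, C) == pytest.approx(
            rate_3d(V0, D, C), rel=1e-12
        )

    def test_2d_tc_to_2d_ratio_is_constant(self):
        expected = math.sqrt(math.pi / 2.0)  # = 2*sqrt(2/pi) / (4/pi)
        for A, D, C in [(1e-18, 1e-10, 1e18), (3e-15, 2.9e-10, 1e20),
                        (1e-16, 5e-12, 1e22)]:
            assert rate_2d_tc(A, D, C) / rate_2d(A, D, C) == pytest.approx(
                expected, rel=1e-12
            )

    def test_3d_smaller_than_2d_for_matched_sphere(self):
        """With A = pi r0^2 and V0 = (4/3) pi r0^3 and r0 << L, the
        pass-through (3D) picture predicts a much smaller rate."""
        r0, D, C = 1e-9, D_REF, 1e20  # L ~ 2e-7 >> r0
        L = mean_separation(C)
        r3 = rate_3d((4 / 3) * math.pi * r0**3, D, C)
        r2 = rate_2d(math.pi * r0**2, D, C)
        assert r3 < r2
        # symbolic ratio (4 pi / 3) * (r0 / L)
        assert r3 / r2 == pytest.approx((4.0 * math.pi / 3.0) * r0 / L, rel=1e-9)


class TestEffectiveFractions:
    def test_area_fraction_values(self):
        assert effective_fraction_from_area(math.pi * 1e-12, 1e-6) == pytest.approx(1.0)
        assert effective_fraction_from_area(3.4e-15, 1.18e-6) == pytest.approx(
            7.77e-4, rel=1e-2
        )
        base = effective_fraction_from_area(1e-16, 1e-6)
        assert effective_fraction_from_area(1e-16, 2e-6) == pytest.approx(base / 4)
        with pytest.raises(ValueError):
            effective_fraction_from_area(1.0, 1e-6)  # larger than neighbour sphere

    def test_volume_fraction_values(self):
        assert effective_fraction_from_volume(1e18, 1e-18) == pytest.approx(1.0)
        assert effective_fraction_from_volume(6.022e17, 1.27e-21) == pytest.approx(
            7.6e-4, rel=1e-2
        )
        assert effective_fraction_from_volume(2e17, 2e-21) == pytest.approx(
            4 * effective_fraction_from_volume(1e17, 1e-21), rel=1e-12
        )
        with pytest.raises(ValueError):
            effective_fraction_from_volume(1e20, 1e-18)


class TestInversion:
    @given(pos_D, pos_C, st.floats(min_value=1e-4, max_value=1e2))
    def test_forward_inverse_round_trip(self, D, C, r):
        # the 0D fraction is only defined up to a = 1
        assume(r / (4.0 * D * C ** (2.0 / 3.0)) <= 1.0)
        for model in INVERTIBLE_MODELS:
            geometry = invert_model(model, r, C, D)
            assert predict_rate(model, geometry, D, C) == pytest.approx(r, rel=1e-12)

    def test_published_cells(self):
        g1 = invert_model(
            ModelId.SMOLUCHOWSKI_1D, 0.63, nanomolar_to_number_density(1.0), D_REF
        )
        assert g1.collision_radius_r0 * 1e9 == pytest.approx(0.29, rel=0.10)
        g2 = invert_model(
            ModelId.DISCRETE_3D, 15.0, nanomolar_to_number_density(100.0), D_REF
        )
        assert g2.collision_volume_V0 * 1e27 == pytest.approx(1.4e4, rel=0.10)

    def test_zero_rate_gives_zero_geometry(self):
        g = invert_model(ModelId.DISCRETE_0D, 0.0, 1e18, D_REF)
        assert g.effective_fraction_a == 0.0

    def test_time_dependent_models_rejected(self):
        with pytest.raises(LookupError):
            invert_model(ModelId.LANGMUIR_SCHAEFER, 1.0, 1e18, D_REF)
        with pytest.raises(LookupError):
            invert_model(ModelId.NAIVE_CONTINUOUS, 1.0, 1e18, D_REF)

    def test_langmuir_schaefer_explicit_time_round_trip(self):
        C, t = 1e19, 0.5
        g = invert_langmuir_schaefer(2.0, C, D_REF, t)
        assert rate_langmuir_schaefer(g.collision_area_A, C, D_REF, t) == pytest.approx(
            2.0, rel=1e-12
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            invert_model(ModelId.DISCRETE_0D, -1.0, 1e18, D_REF)


class TestCylinderConventions:
    def test_published_radii(self):
        assert cylinder_radius_from_area(3400e-18, 1e-6) * 1e9 == pytest.approx(3.4)
        assert cylinder_radius_from_area(170e-18, 1e-6) * 1e9 == pytest.approx(0.17)
        assert cylinder_radius_from_volume(130e4 * 1e-27, 1e-6) * 1e9 == pytest.approx(
            36.0, rel=2e-2
        )
        assert cylinder_radius_from_volume(1.4e4 * 1e-27, 1e-6) * 1e9 == pytest.approx(
            3.74, rel=1e-2
        )

    def test_scalings(self):
        assert cylinder_radius_from_area(1e-18, 2e-6) == pytest.approx(
            cylinder_radius_from_area(1e-18, 1e-6) / 2
        )
        assert cylinder_radius_from_volume(4e-27, 1e-6) == pytest.approx(
            2 * cylinder_radius_from_volume(1e-27, 1e-6)
        )


class TestDimensionalRegistry:
    def test_concentration_exponents(self):
        assert dimensional_signature(ModelId.SMOLUCHOWSKI_1D).concentration_exponent == 1
        assert dimensional_signature(ModelId.DISCRETE_3D).concentration_exponent == Fraction(5, 3)
        assert dimensional_signature(ModelId.DISCRETE_0D).concentration_exponent == Fraction(2, 3)
        assert dimensional_signature(ModelId.NAIVE_CONTINUOUS).diffusion_exponent == 0

    def test_every_model_has_units_of_per_second(self):
        for model in ModelId:
            m_exp, s_exp = dimensional_signature(model).si_unit_exponents()
            assert m_exp == 0, model
            assert s_exp == -1, model

    def test_registry_serializes(self):
        entries = registry_to_json()
        assert {e["model"] for e in entries} == {m.value for m in ModelId}
        assert all("coefficient" in e for e in entries)


class TestThermodynamicUtilities:
    def test_arrhenius(self):
        assert arrhenius_pseudo_first_order(5.0, 0.0, 300.0) == 5.0
        assert arrhenius_pseudo_first_order(
            5.0, GAS_CONSTANT * 300.0, 300.0
        ) == pytest.approx(5.0 / math.e, rel=1e-12)
        # high-T limit: Ea/(R T) ~ 1.2e-9 leaves a matching residual
        assert arrhenius_pseudo_first_order(5.0, 1e4, 1e12) == pytest.approx(
            5.0, rel=1e-8
        )
        with pytest.raises(ValueError):
            arrhenius_pseudo_first_order(5.0, 1e4, 0.0)

    def test_equilibrium_constant(self):
        assert equilibrium_constant_from_free_energy(0.0, 298.0) == pytest.approx(1.0)
        dG = -GAS_CONSTANT * 298.0 * math.log(10.0)
        assert equilibrium_constant_from_free_energy(dG, 298.0) == pytest.approx(10.0)
        ka = equilibrium_constant_from_free_energy(-3e4, 298.0)
        assert ka * dissociation_constant(ka) == pytest.approx(1.0, rel=1e-12)
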