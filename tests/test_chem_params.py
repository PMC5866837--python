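"""Chemical parameter derivations: permeability regression, QPPR, absorption."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qivive.chem_params import (
    ChemicalParams,
    PappUnitConvention,
    absorption_rate,
    papp_invivo_from_caco2,
    papp_regression,
    partition_coefficients_qppr,
)
from qivive.errors import ConfigurationError, DomainError


class TestPappRegression:
    def test_unit_input_gives_intercept(self):
        # log(out) = 0.6836*log(1) - 0.5579 => 10**-0.5579
        assert papp_regression(1.0) == pytest.approx(10**-0.5579, rel=1e-12)
        assert papp_regression(1.0) == pytest.approx(0.2767, rel=1e-3)

    def test_e2_value_under_default_convention(self):
        # Papp,Caco-2 = 17e-6 cm/s: regression output 10**(0.6836*log10(17)-0.5579)
        # read in 1e-4 cm/s, converted to cm/h
        expected = 10 ** (0.6836 * math.log10(17) - 0.5579) * 1e-4 * 3600
        assert papp_invivo_from_caco2(17.0) == pytest.approx(expected, rel=1e-12)
        assert papp_invivo_from_caco2(17.0) == pytest.approx(0.691, rel=1e-3)

    def test_same_units_convention_is_100x_smaller(self):
        default = papp_invivo_from_caco2(17.0, PappUnitConvention.CACO2_1E6_TO_INVIVO_1E4)
        literal = papp_invivo_from_caco2(17.0, PappUnitConvention.SAME_UNITS)
        assert literal == pytest.approx(default / 100.0, rel=1e-12)

    @given(
        lo=st.floats(min_value=1e-3, max_value=1e3),
        factor=st.floats(min_value=1.0 + 1e-6, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, lo, factor):
        assert papp_invivo_from_caco2(lo * factor) > papp_invivo_from_caco2(lo)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(DomainError):
            papp_invivo_from_caco2(0.0)
        with pytest.raises(DomainError):
            papp_invivo_from_caco2(-1.0)


class TestQppr:
    def test_blood_like_tissue_partitions_at_unity(self):
        blood = {"lipid": 0.0033, "water": 0.83}
        table = {name: dict(blood) for name in
                 ("blood", "liver", "fat", "richly_perfused", "slowly_perfused")}
        for log_pow in (-2.0, 0.0, 3.32, 4.01, 8.0):
            pc = partition_coefficients_qppr(log_pow, table)
            assert pc.liver == pytest.approx(1.0, abs=1e-12)
            assert pc.fat == pytest.approx(1.0, abs=1e-12)
            assert pc.slowly_perfused == pytest.approx(1.0, abs=1e-12)

    def test_fat_pc_monotone_in_lipophilicity(self):
        assert partition_coefficients_qppr(4.01).fat > partition_coefficients_qppr(3.32).fat

    def test_deterministic(self):
        a = partition_coefficients_qppr(4.01)
        b = partition_coefficients_qppr(4.01)
        assert (a.liver, a.fat, a.richly_perfused, a.slowly_perfused) == (
            b.liver, b.fat, b.richly_perfused, b.slowly_perfused)

    def test_missing_tissue_is_configuration_error(self):
        table = {"blood": {"lipid": 0.0033, "water": 0.83}}
        with pytest.raises(ConfigurationError):
            partition_coefficients_qppr(4.01, table)

    def test_explicit_pcs_bypass_qppr(self, e2):
        from dataclasses import replace
        from qivive.chem_params import PartitionCoefficients

        explicit = PartitionCoefficients(liver=2.0, fat=5.0, richly_perfused=2.0,
                                         slowly_perfused=1.0)
        chem = replace(e2, partition_coefficients=explicit)
        assert chem.resolve_pc() is explicit


class TestAbsorptionRate:
    def test_hand_unit_conversion(self):
        # 0.1 cm/h * 10 cm^2 * 1 mM (= 1 umol/cm^3) = 1 umol/h
        assert absorption_rate(0.1, 10.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_concentration_gives_zero(self):
        assert absorption_rate(0.5, 100.0, 0.0) == 0.0
        assert absorption_rate(0.0, 100.0, 3.0) == 0.0

    @given(
        papp=st.floats(min_value=0, max_value=10),
        sa=st.floats(min_value=0, max_value=1e3),
        c=st.floats(min_value=0, max_value=1e2),
    )
    @settings(max_examples=50, deadline=None)
    def test_bilinear(self, papp, sa, c):
        assert absorption_rate(papp, sa, 2 * c) == pytest.approx(
            2 * absorption_rate(papp, sa, c), rel=1e-9, abs=1e-12)
        assert absorption_rate(2 * papp, sa, c) == pytest.approx(
            2 * absorption_rate(papp, sa, c), rel=1e-9, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            absorption_rate(-0.1, 10.0, 1.0)


class TestChemicalParams:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(DomainError):
            ChemicalParams(name="x", mw=100.0, log_pow=2.0, papp_caco2=5.0,
                           clint_invitro=10.0, fub_serum=1.5)

    def test_negative_clint_rejected(self):
        with pytest.raises(DomainError):
            ChemicalParams(name="x", mw=100.0, log_pow=2.0, papp_caco2=5.0,
                           clint_invitro=-1.0, fub_serum=0.5)
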