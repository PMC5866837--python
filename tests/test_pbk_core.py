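"""Kinetic-model simulation: conservation, linearity, convergence."""

from dataclasses import replace

import numpy as np
import pytest

from qivive.errors import ConfigurationError, DomainError
from qivive.pbk_core import (
    ExposureScenario,
    PhysiologyParams,
    SolverSettings,
    cmax_auc,
    simulate,
)


def oral(dose, duration=24.0):
    return ExposureScenario(route="oral", dose_mg_per_kg=dose, duration_h=duration)


def iv(dose, duration=24.0):
    return ExposureScenario(route="iv", dose_mg_per_kg=dose, duration_h=duration)


class TestConservation:
    def test_zero_dose_is_identically_zero(self, e2, phys):
        result = simulate(e2, None, phys, oral(0.0))
        assert result.cmax == 0.0
        assert np.all(result.conc_blood == 0.0)
        assert np.all(result.amounts.to_numpy() == 0.0)

    def test_iv_without_clearance_conserves_dose_in_body(self, e2, phys):
        chem = replace(e2, clint_invitro=0.0)
        result = simulate(chem, None, phys, iv(0.1))
        body = result.amounts[["blood", "liver", "fat", "richly_perfused",
                               "slowly_perfused"]].sum(axis=1)
        assert np.allclose(body, result.dose_umol, rtol=1e-7)
        assert result.amounts["metabolized"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_below_tolerance_on_all_default_scenarios(self, config):
        for name, scenario in config.scenarios:
            result = simulate(config.chemicals[name], None, config.physiology, scenario)
            assert result.mass_balance_error < 1e-6

    def test_states_nonnegative(self, bpa, phys):
        result = simulate(bpa, None, phys, oral(10.0))
        assert result.amounts.to_numpy().min() > -1e-9

    def test_no_absorption_no_clearance_keeps_lumen_mass_and_blood_empty(self, e2, phys):
        chem = replace(e2, clint_invitro=0.0, papp_caco2=1e-12)
        result = simulate(chem, None, phys, oral(1.0))
        gut = result.amounts[[c for c in result.amounts.columns
                              if c.startswith(("lumen", "stomach", "unabsorbed"))]].sum(axis=1)
        assert np.allclose(gut, result.dose_umol, rtol=1e-6)
        # residual permeability is ~1e-9 cm/h, so blood stays ~7 orders below
        # the dose-equivalent concentration
        assert result.cmax < 1e-6

    def test_oral_dose_fully_accounted_at_late_time(self, e2, phys):
        result = simulate(e2, None, phys, oral(0.02, duration=48.0))
        final = result.amounts.iloc[-1]
        cleared = final["metabolized"] + final["unabsorbed"]
        assert cleared == pytest.approx(result.dose_umol, rel=1e-3)


class TestLinearity:
    def test_cmax_proportional_to_dose(self, e2, phys):
        lo = simulate(e2, None, phys, oral(0.02))
        hi = simulate(e2, None, phys, oral(0.2))
        assert hi.cmax / lo.cmax == pytest.approx(10.0, rel=1e-4)

    def test_bpa_10x_dose_pair(self, bpa, phys):
        lo = simulate(bpa, None, phys, oral(10.0))
        hi = simulate(bpa, None, phys, oral(100.0))
        assert hi.cmax / lo.cmax == pytest.approx(10.0, rel=1e-4)


class TestSolver:
    def test_halving_tolerances_changes_cmax_by_less_than_0p1_percent(self, e2, phys):
        base = simulate(e2, None, phys, oral(0.02), SolverSettings())
        tight = simulate(
            e2, None, phys, oral(0.02),
            SolverSettings(rtol=0.5e-8, atol=0.5e-12),
        )
        assert tight.cmax == pytest.approx(base.cmax, rel=1e-3)

    def test_iv_initial_blood_concentration_matches_bolus(self, e2, phys):
        result = simulate(e2, None, phys, iv(0.1))
        vb = phys.vbc * phys.body_weight
        assert result.conc_blood[0] == pytest.approx(result.dose_umol / vb, rel=1e-6)
        # IV peak is at t=0 and decays from there
        assert result.cmax == pytest.approx(result.conc_blood[0], rel=1e-6)


class TestCmaxAuc:
    def test_constant_concentration(self):
        times = np.linspace(0, 10, 101)
        conc = np.full_like(times, 3.0)
        cmax, tmax, auc = cmax_auc(times, conc)
        assert cmax == 3.0
        assert auc == pytest.approx(30.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            cmax_auc(np.array([]), np.array([]))


class TestPhysiologyValidation:
    def test_remainders_keep_sum_constraints(self):
        phys = PhysiologyParams()
        assert phys.vlc + phys.vfc + phys.vbc + phys.vrc + phys.vsc == pytest.approx(
            phys.perfused_fraction)
        assert phys.qlc + phys.qfc + phys.qrc + phys.qsc == pytest.approx(1.0)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            PhysiologyParams(vfc=0.9)
        with pytest.raises(ConfigurationError):
            PhysiologyParams(qrc=0.8)

    def test_perturbing_one_fraction_rebalances_the_remainder(self):
        base = PhysiologyParams()
        bumped = replace(base, vrc=base.vrc * 1.05)
        assert bumped.vsc == pytest.approx(base.vsc - 0.05 * base.vrc)
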