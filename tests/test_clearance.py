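"""Substrate-depletion fitting and clearance scaling."""

import numpy as np
import pandas as pd
import pytest

from qivive.clearance import (
    DEPLETION_TIME_GRID_MIN,
    DepletionSeries,
    check_substrate_below_km,
    clint_invitro,
    fit_depletion,
    scale_clint_to_liver,
    sum_pathway_clints,
)
from qivive.errors import DataError, DomainError
from qivive.fixtures import make_depletion


def exact_series(k, **kw):
    t = np.array(DEPLETION_TIME_GRID_MIN)
    return DepletionSeries(times=t, ratios=np.exp(-k * t)[None, :], **kw)


class TestFitDepletion:
    def test_exact_exponential_recovered_to_machine_precision(self):
        result = fit_depletion(exact_series(0.05))
        assert result.k == pytest.approx(0.05, rel=1e-12)
        assert result.window == (0, len(DEPLETION_TIME_GRID_MIN))
        assert result.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert not result.no_depletion

    def test_flat_series_flags_no_depletion(self):
        result = fit_depletion(exact_series(0.0))
        assert result.k == 0.0
        assert result.clint_invitro == 0.0
        assert result.no_depletion

    def test_noisy_recovery_within_10_percent(self):
        series, truth = make_depletion(k_true=0.0875, noise_cv=0.05, n_replicates=3, seed=7)
        result = fit_depletion(series)
        assert result.k == pytest.approx(truth["k_true"], rel=0.10)

    def test_replicates_pooled_on_log_scale(self):
        t = np.array(DEPLETION_TIME_GRID_MIN)
        # two replicates scaled by reciprocal factors: geometric mean is exact
        clean = np.exp(-0.1 * t)
        ratios = np.vstack([clean * 1.25, clean / 1.25])
        ratios[:, 0] = 1.0
        result = fit_depletion(DepletionSeries(times=t, ratios=ratios))
        # only the t=0 forcing perturbs the slope slightly
        assert result.k == pytest.approx(0.1, rel=0.02)

    def test_rescaling_late_ratios_moves_intercept_not_slope(self):
        t = np.array(DEPLETION_TIME_GRID_MIN)
        base = np.exp(-0.08 * t)
        scaled = base * 0.8
        r1 = fit_depletion(DepletionSeries(times=t, ratios=base[None, :]))
        r2 = fit_depletion(DepletionSeries(times=t, ratios=scaled[None, :]))
        assert r2.k == pytest.approx(r1.k, rel=1e-9)
        assert r2.log_intercept == pytest.approx(r1.log_intercept + np.log(0.8), rel=1e-9)

    def test_nonpositive_ratio_rejected(self):
        t = np.array(DEPLETION_TIME_GRID_MIN)
        bad = np.exp(-0.05 * t)
        bad[3] = 0.0
        with pytest.raises(DataError):
            DepletionSeries(times=t, ratios=bad[None, :])

    def test_from_frame_round_trip(self):
        series, _ = make_depletion(k_true=0.05, seed=1)
        rows = [
            {"time_min": t, "replicate": r, "ratio": series.ratios[r, j]}
            for r in range(series.ratios.shape[0])
            for j, t in enumerate(series.times)
        ]
        rebuilt = DepletionSeries.from_frame(pd.DataFrame(rows))
        assert fit_depletion(rebuilt).k == pytest.approx(fit_depletion(series).k, rel=1e-12)


class TestClintInvitro:
    def test_printed_male_rat_value(self):
        # V = 200 uL, P = 0.5 mg/mL * 0.2 mL = 0.1 mg, k = 0.0875/min
        assert clint_invitro(0.0875, 200.0, 0.1) == pytest.approx(175.0, rel=1e-12)

    def test_zero_rate_gives_zero(self):
        assert clint_invitro(0.0, 200.0, 0.1) == 0.0

    def test_doubling_protein_halves_clint(self):
        assert clint_invitro(0.1, 200.0, 0.2) == pytest.approx(
            clint_invitro(0.1, 200.0, 0.1) / 2, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            clint_invitro(0.1, 0.0, 0.1)
        with pytest.raises(DomainError):
            clint_invitro(-0.1, 200.0, 0.1)


class TestPathwaySums:
    def test_e2_male_pathway_sum(self):
        # NADPH + UDPGA + PAPS, acetyl-CoA incubation yields no clearance
        assert sum_pathway_clints([154.7, 23.3, 4.4, None]) == pytest.approx(182.4, abs=1e-9)

    def test_bpa_male_pathway_sum(self):
        assert sum_pathway_clints([60.0, 339.7, 3.4, None]) == pytest.approx(403.1, abs=1e-9)

    def test_empty_list_is_zero(self):
        assert sum_pathway_clints([]) == 0.0

    def test_negative_value_rejected(self):
        with pytest.raises(DataError):
            sum_pathway_clints([10.0, -1.0])

    def test_additivity_of_fitted_pathway_clints(self):
        # depletion with the summed rate equals the sum of single-pathway fits
        ks = [0.05, 0.02, 0.01]
        singles = [fit_depletion(exact_series(k)).clint_invitro for k in ks]
        combined = fit_depletion(exact_series(sum(ks))).clint_invitro
        assert combined == pytest.approx(sum_pathway_clints(singles), rel=1e-9)


class TestLiverScaling:
    def test_hand_unit_chain(self):
        # 175 uL/min/mg * 60 / 1e6 * (87 g/kg * 0.0085 kg * 1000 mg/g) = 7.76 L/h
        assert scale_clint_to_liver(175.0, 87.0, 0.0085) == pytest.approx(7.765, rel=1e-3)

    def test_zero_clint_gives_zero(self):
        assert scale_clint_to_liver(0.0, 87.0, 0.0085) == 0.0

    def test_linear_in_liver_mass(self):
        assert scale_clint_to_liver(100.0, 87.0, 0.017) == pytest.approx(
            2 * scale_clint_to_liver(100.0, 87.0, 0.0085), rel=1e-12)

    def test_nonpositive_liver_mass_rejected(self):
        with pytest.raises(DomainError):
            scale_clint_to_liver(100.0, 87.0, 0.0)


class TestKmCheck:
    def test_below_km(self):
        series, _ = make_depletion(k_true=0.05, seed=0, substrate_conc_um=3.0,
                                   km_lower_bound_um=18.0)
        assert check_substrate_below_km(series) is True

    def test_at_km_boundary_is_false(self):
        series, _ = make_depletion(k_true=0.05, seed=0, substrate_conc_um=18.0,
                                   km_lower_bound_um=18.0)
        assert check_substrate_below_km(series) is False

    def test_missing_km_is_undetermined(self):
        series, _ = make_depletion(k_true=0.05, seed=0)
        assert check_substrate_below_km(series) is None
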