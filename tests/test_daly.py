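"""DALY model: discounting, arm decomposition, thresholds, calibration."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pedcea.daly import (
    CalibrationError,
    DalyDomainError,
    DalyParams,
    calibrate_adjustments,
    cost_per_daly,
    dalys_averted,
    dalys_no_treatment,
    discounted_years,
    evaluate,
    sensitivity_grid,
    who_choice_classify,
)


class TestDiscountedYears:
    def test_undiscounted_limit_returns_horizon(self):
        assert discounted_years(65.66, 0.0) == pytest.approx(65.66)

    @pytest.mark.parametrize("L,r,expected", [(65.66, 0.03, 28.69), (65.66, 0.06, 16.34)])
    def test_matches_quadrature_at_published_inputs(self, L, r, expected):
        oracle, _ = quad(lambda t: math.exp(-r * t), 0.0, L)
        assert discounted_years(L, r) == pytest.approx(oracle, rel=1e-9)
        assert discounted_years(L, r) == pytest.approx(expected, abs=0.01)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        L=st.floats(min_value=0.0, max_value=100.0),
        r=st.floats(min_value=0.0, max_value=0.2),
    )
    def test_matches_quadrature_everywhere(self, L, r):
        oracle, _ = quad(lambda t: math.exp(-r * t), 0.0, L)
        assert discounted_years(L, r) == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_strictly_decreasing_in_rate(self):
        vals = [discounted_years(50.0, r) for r in (0.0, 0.01, 0.03, 0.06, 0.1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("L,r", [(-1.0, 0.03), (10.0, -0.01)])
    def test_negative_inputs_rejected(self, L, r):
        with pytest.raises(DalyDomainError):
            discounted_years(L, r)


class TestNoTreatmentBurden:
    def test_undiscounted_is_remaining_life_expectancy(self):
        p = DalyParams(age_at_dx=6.4, os5=0.5, discount_rate=0.0)
        assert dalys_no_treatment(p) == pytest.approx(72.06 - 6.4)

    def test_discounted_matches_integral(self):
        p = DalyParams(age_at_dx=6.4, os5=0.5, discount_rate=0.03)
        oracle, _ = quad(lambda t: math.exp(-0.03 * t), 0.0, 65.66)
        assert dalys_no_treatment(p) == pytest.approx(oracle, rel=1e-9)
        assert dalys_no_treatment(p) == pytest.approx(28.69, abs=0.01)

    def test_extreme_discounting_drives_burden_to_zero(self):
        p = DalyParams(age_at_dx=6.4, os5=0.5, discount_rate=50.0)
        assert dalys_no_treatment(p) < 0.05

    def test_age_beyond_life_expectancy_rejected(self):
        with pytest.raises(DalyDomainError):
            DalyParams(age_at_dx=80.0, os5=0.5)


class TestDalysAverted:
    def test_futile_treatment_averts_nothing(self):
        # no survivors, no treatment disability: both arms identical
        p = DalyParams(age_at_dx=6.4, os5=0.0, dw_tx=0.0)
        assert dalys_averted(p).dalys_averted == pytest.approx(0.0, abs=1e-12)

    def test_perfect_cure_averts_whole_untreated_burden(self):
        p = DalyParams(
            age_at_dx=6.4, os5=1.0, dw_tx=0.0, d_late=0.0, le_reduction=0.0
        )
        res = dalys_averted(p)
        assert res.dalys_averted == pytest.approx(dalys_no_treatment(p), rel=1e-12)

    def test_decomposition_identity(self, all_cancers_params):
        res = dalys_averted(all_cancers_params)
        assert res.dalys_averted == pytest.approx(
            res.dalys_no_tx - res.dalys_tx, rel=1e-12
        )

    def test_all_cancers_calibration_oracle(self, all_cancers_params, all_cancers_cost):
        # implied by the published pair: $19,799 / $1384 per DALY ~ 14.3
        res = dalys_averted(all_cancers_params)
        assert res.dalys_averted == pytest.approx(14.3, abs=0.1)

    def test_monotone_in_every_parameter(self):
        base = dict(age_at_dx=6.4, os5=0.6, discount_rate=0.03,
                    dw_tx=0.2, d_late=0.2, le_reduction=0.1)
        grid = {
            "os5": ([0.2, 0.5, 0.8], +1),
            "discount_rate": ([0.0, 0.03, 0.06], -1),
            "d_late": ([0.0, 0.2, 0.4], -1),
            "le_reduction": ([0.0, 0.15, 0.30], -1),
            "dw_tx": ([0.0, 0.2, 0.4], -1),
        }
        for name, (values, sign) in grid.items():
            out = [
                dalys_averted(DalyParams(**{**base, name: v})).dalys_averted
                for v in values
            ]
            diffs = np.diff(out) * sign
            assert np.all(diffs > 0), f"not monotone in {name}: {out}"

    def test_reduced_lifespan_shorter_than_treatment_rejected(self):
        p = DalyParams(age_at_dx=6.4, os5=0.5, le_reduction=0.99, tx_duration=2.0)
        with pytest.raises(DalyDomainError):
            dalys_averted(p)


class TestCostPerDaly:
    def test_zero_cost_and_linearity(self):
        assert cost_per_daly(0.0, 14.31) == 0.0
        assert cost_per_daly(19799.0, 14.31) == pytest.approx(1383.6, abs=0.1)
        assert cost_per_daly(2 * 19799.0, 14.31) == pytest.approx(
            2 * cost_per_daly(19799.0, 14.31)
        )

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(DalyDomainError):
            cost_per_daly(100.0, 0.0)

    def test_invariant_to_joint_currency_rescaling(self, all_cancers_params):
        a = evaluate(all_cancers_params, 19799.0, gdp_per_capita=3019.0)
        b = evaluate(all_cancers_params, 19799.0 * 16.77, gdp_per_capita=3019.0 * 16.77)
        assert a.gdp_ratio == pytest.approx(b.gdp_ratio, rel=1e-12)
        assert a.classification == b.classification


class TestWhoChoiceClassification:
    @pytest.mark.parametrize(
        "ratio,label",
        [
            (0.0, "very cost-effective"),
            (0.5, "very cost-effective"),
            (0.999, "very cost-effective"),
            (1.0, "cost-effective"),       # boundary: less favourable label
            (2.9, "cost-effective"),
            (3.0, "not cost-effective"),   # boundary: less favourable label
            (10.0, "not cost-effective"),
        ],
    )
    def test_threshold_rule(self, ratio, label):
        assert who_choice_classify(ratio) == label

    def test_negative_ratio_rejected(self):
        with pytest.raises(DalyDomainError):
            who_choice_classify(-0.1)


class TestSensitivityGrid:
    def test_full_cross_product_of_cells(self, all_cancers_params, all_cancers_cost):
        grid = sensitivity_grid(all_cancers_params, all_cancers_cost)
        assert len(grid) == 3 * 3 * 2

    def test_cells_equal_independent_evaluations(
        self, all_cancers_params, all_cancers_cost
    ):
        grid = sensitivity_grid(all_cancers_params, all_cancers_cost)
        for _, cell in grid.iterrows():
            p = replace(
                all_cancers_params,
                discount_rate=cell["discount_rate"],
                le_reduction=cell["le_reduction"],
                d_late=all_cancers_params.d_late if cell["late_decrement_on"] else 0.0,
            )
            res = evaluate(p, all_cancers_cost)
            assert cell["cost_per_daly"] == pytest.approx(res.cost_per_daly, rel=1e-12)
            assert cell["classification"] == res.classification

    def test_undiscounted_cells_are_cheapest_per_daly(
        self, all_cancers_params, all_cancers_cost
    ):
        grid = sensitivity_grid(all_cancers_params, all_cancers_cost)
        for (rho, dec), sub in grid.groupby(["le_reduction", "late_decrement_on"]):
            ordered = sub.sort_values("discount_rate")["cost_per_daly"].to_numpy()
            assert np.all(np.diff(ordered) > 0)

    def test_larger_le_reduction_is_costlier_per_daly(
        self, all_cancers_params, all_cancers_cost
    ):
        grid = sensitivity_grid(all_cancers_params, all_cancers_cost)
        for (r, dec), sub in grid.groupby(["discount_rate", "late_decrement_on"]):
            ordered = sub.sort_values("le_reduction")["cost_per_daly"].to_numpy()
            assert np.all(np.diff(ordered) > 0)


class TestCalibration:
    def test_round_trip_recovery_of_known_parameters(self, all_cancers_cost):
        truth = DalyParams(age_at_dx=6.4, os5=0.731, d_late=0.25, le_reduction=0.18)
        obs = {
            r: evaluate(replace(truth, discount_rate=r), all_cancers_cost).cost_per_daly
            for r in (0.03, 0.06)
        }
        d, rho, resid = calibrate_adjustments(all_cancers_cost, obs, truth)
        assert d == pytest.approx(0.25, abs=1e-6)
        assert rho == pytest.approx(0.18, abs=1e-6)
        assert resid < 1e-8

    def test_single_observation_solves_late_decrement_only(self, all_cancers_cost):
        fixed = DalyParams(age_at_dx=6.4, os5=0.731, le_reduction=0.0)
        d, rho, resid = calibrate_adjustments(
            all_cancers_cost, {0.03: 1384.0}, fixed
        )
        assert rho == 0.0
        assert resid < 1e-8
        check = evaluate(replace(fixed, d_late=d), all_cancers_cost)
        assert check.cost_per_daly == pytest.approx(1384.0, rel=1e-6)

    def test_package_defaults_are_the_two_point_calibration(self, all_cancers_cost):
        from pedcea.daly import D_LATE_DEFAULT, LE_REDUCTION_DEFAULT

        fixed = DalyParams(age_at_dx=6.4, os5=0.731)
        d, rho, resid = calibrate_adjustments(
            all_cancers_cost, {0.03: 1384.0, 0.06: 2347.0}, fixed
        )
        assert d == pytest.approx(D_LATE_DEFAULT, abs=5e-5)
        assert rho == pytest.approx(LE_REDUCTION_DEFAULT, abs=5e-5)
        assert resid < 1e-8

    def test_inconsistent_observations_fail(self, all_cancers_cost):
        fixed = DalyParams(age_at_dx=6.4, os5=0.731)
        # a cost/DALY this low would need a negative decrement
        with pytest.raises(CalibrationError):
            calibrate_adjustments(all_cancers_cost, {0.03: 100.0}, fixed)
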