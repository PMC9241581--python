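"""Survival curves, hazard-ratio algebra, MLE fitting and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from nsclc_cea.params import LifeTable, WeibullParams
from nsclc_cea.survival import (
    FAMILY_ORDER,
    FitResult,
    SurvivalDataset,
    apply_hazard_ratio,
    cycle_transition_probability,
    fit_all_families,
    fit_parametric,
    select_model,
    weekly_background_mortality,
    weibull_mean,
    weibull_survival,
)
from nsclc_cea.synthetic import SyntheticSpec, gen_censored_weibull

PFS_REF = WeibullParams(scale=0.0474, shape=1.5590)
OS_REF = WeibullParams(scale=0.0075, shape=1.3601)


class TestWeibullSurvival:
    def test_starts_at_one(self):
        assert weibull_survival(PFS_REF, 0.0) == 1.0

    def test_median_matches_bisection_oracle(self):
        # independent root-finding oracle for S(t) = 1/2
        t_half = brentq(
            lambda t: math.exp(-0.0474 * t**1.5590) - 0.5, 0.01, 100.0
        )
        assert t_half == pytest.approx((math.log(2) / 0.0474) ** (1 / 1.5590), rel=1e-9)
        assert weibull_survival(PFS_REF, t_half) == pytest.approx(0.5, abs=1e-12)
        assert t_half == pytest.approx(5.589, abs=1e-3)

    def test_one_year_overall_survival_direct_evaluation(self):
        # exp(-0.0075 * 12**1.3601) evaluated independently
        expected = math.exp(-0.0075 * math.exp(1.3601 * math.log(12.0)))
        assert expected == pytest.approx(0.8023, abs=5e-4)
        assert weibull_survival(OS_REF, 12.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(PFS_REF, -1.0)

    def test_non_increasing_in_time(self):
        grid = np.linspace(0.0, 120.0, 500)
        s = weibull_survival(PFS_REF, grid)
        assert np.all(np.diff(s) <= 0)

    def test_mean_quadrature_matches_closed_form(self):
        # lifetime mean of the reference OS curve: integral of S vs Gamma form
        numeric, _ = quad(lambda t: weibull_survival(OS_REF, t), 0.0, 600.0)
        assert numeric == pytest.approx(weibull_mean(OS_REF), rel=1e-6)
        assert weibull_mean(OS_REF) == pytest.approx(33.5, abs=0.5)  # months


class TestApplyHazardRatio:
    def test_identity_at_unit_ratio(self):
        out = apply_hazard_ratio(PFS_REF, 1.0)
        assert (out.scale, out.shape) == (PFS_REF.scale, PFS_REF.shape)

    def test_printed_gefitinib_example(self):
        out = apply_hazard_ratio(PFS_REF, 0.37)
        assert out.scale == pytest.approx(0.017538, rel=1e-6)
        assert out.shape == 1.5590

    def test_protective_ratio_raises_survival_everywhere(self):
        out = apply_hazard_ratio(PFS_REF, 0.37)
        grid = np.linspace(0.1, 120.0, 200)
        assert np.all(
            weibull_survival(out, grid) >= weibull_survival(PFS_REF, grid)
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        hr1=st.floats(0.1, 3.0),
        hr2=st.floats(0.1, 3.0),
    )
    def test_composition_multiplies_ratios(self, hr1, hr2):
        once = apply_hazard_ratio(PFS_REF, hr1 * hr2)
        twice = apply_hazard_ratio(apply_hazard_ratio(PFS_REF, hr1), hr2)
        assert twice.scale == pytest.approx(once.scale, rel=1e-12)
        assert twice.shape == once.shape

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(PFS_REF, 0.0)


class TestCycleTransitionProbability:
    def test_constant_hazard_closed_form(self):
        par = WeibullParams(scale=0.1, shape=1.0)
        expected = 1.0 - math.exp(-0.1)
        for k in (0, 1, 10, 500):
            assert cycle_transition_probability(par, k, 1.0) == pytest.approx(
                expected, rel=1e-12
            )

    def test_increasing_hazard_gives_increasing_probabilities(self):
        probs = [
            cycle_transition_probability(PFS_REF, k, 7 / 30.4375) for k in range(300)
        ]
        assert all(0.0 <= p < 1.0 for p in probs)
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_first_week_direct_evaluation(self):
        # 1 - S(one week) evaluated independently of the implementation
        dt = 7 / 30.4375
        expected = 1.0 - math.exp(-0.0474 * dt**1.5590)
        assert expected == pytest.approx(0.00479, abs=5e-5)
        assert cycle_transition_probability(PFS_REF, 0, dt) == pytest.approx(
            expected, rel=1e-9
        )

    def test_late_cycles_stay_below_one(self):
        # survival underflows far beyond the horizon; the ratio must not
        p = cycle_transition_probability(PFS_REF, 5000, 7 / 30.4375)
        assert 0.0 <= p < 1.0


class TestWeeklyBackgroundMortality:
    def test_boundary_probabilities(self):
        lt = LifeTable(np.array([60]), np.array([0.0]))
        assert weekly_background_mortality(lt, 60) == 0.0
        lt1 = LifeTable(np.array([60]), np.array([1.0]))
        assert weekly_background_mortality(lt1, 60) == 1.0

    def test_two_percent_annual_example(self):
        lt = LifeTable(np.array([70]), np.array([0.02]))
        assert weekly_background_mortality(lt, 70.5) == pytest.approx(
            1.0 - 0.98 ** (1 / 52.18), rel=1e-4
        )
        assert weekly_background_mortality(lt, 70.5) == pytest.approx(0.000387, abs=2e-6)


class TestFitting:
    def test_parameter_recovery_at_n5000(self):
        data = gen_censored_weibull(
            SyntheticSpec(seed=0, n_patients=5000, censoring_fraction=0.2)
        )
        fit = fit_parametric(data, "weibull")
        assert fit.params["scale"] == pytest.approx(0.0474, rel=0.05)
        assert fit.params["shape"] == pytest.approx(1.5590, rel=0.05)

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (500, 5000):
            scales = []
            for s in range(8):
                data = gen_censored_weibull(
                    SyntheticSpec(seed=3000 + s, n_patients=n, censoring_fraction=0.2)
                )
                scales.append(fit_parametric(data, "weibull").params["scale"])
            errs[n] = np.mean(np.abs(np.array(scales) - 0.0474))
        assert errs[5000] < errs[500]

    def test_weibull_nests_exponential(self):
        rng = np.random.default_rng(5)
        data = SurvivalDataset(
            rng.exponential(10.0, size=4000) + 1e-9, np.ones(4000, dtype=int)
        )
        fit = fit_parametric(data, "weibull")
        assert fit.params["shape"] == pytest.approx(1.0, abs=0.05)
        expo = fit_parametric(data, "exponential")
        assert fit.loglik >= expo.loglik - 1e-6

    def test_information_criteria_definitions(self):
        data = gen_censored_weibull(
            SyntheticSpec(seed=1, n_patients=200, censoring_fraction=0.2)
        )
        fit = fit_parametric(data, "weibull")
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 2)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 2 * math.log(200))

    def test_all_censored_rejected(self):
        data = SurvivalDataset(np.linspace(1, 10, 20), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="censored"):
            fit_parametric(data, "weibull")

    def test_too_few_observations_rejected(self):
        data = SurvivalDataset(np.linspace(1, 5, 5), np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="10"):
            fit_parametric(data, "weibull")


class TestSelectModel:
    def test_minimum_bic_wins(self):
        fits = [
            FitResult("exponential", {}, 0.0, 100.0, 100.0, 50, 50),
            FitResult("weibull", {}, 0.0, 90.0, 90.0, 50, 50),
            FitResult("gompertz", {}, 0.0, 95.0, 95.0, 50, 50),
        ]
        assert select_model(fits).bic == 90.0

    def test_tie_broken_by_aic_then_family_order(self):
        fits = [
            FitResult("lognormal", {}, 0.0, 80.0, 90.0, 50, 50),
            FitResult("weibull", {}, 0.0, 85.0, 90.0, 50, 50),
        ]
        assert select_model(fits).family == "lognormal"  # lower AIC
        fits_equal = [
            FitResult("lognormal", {}, 0.0, 90.0, 90.0, 50, 50),
            FitResult("weibull", {}, 0.0, 90.0, 90.0, 50, 50),
        ]
        assert select_model(fits_equal).family == "weibull"  # earlier in order
        assert FAMILY_ORDER.index("weibull") < FAMILY_ORDER.index("lognormal")

    def test_single_fit_returned(self):
        only = FitResult("gompertz", {}, 0.0, 1.0, 1.0, 50, 50)
        assert select_model([only]) is only

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_true_family_selected_in_most_replicates(self):
        wins = 0
        n_rep = 50
        for s in range(n_rep):
            data = gen_censored_weibull(
                SyntheticSpec(seed=1000 + s, n_patients=1500, censoring_fraction=0.2)
            )
            wins += select_model(fit_all_families(data)).family == "weibull"
        assert wins >= 0.9 * n_rep
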