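"""One-way DSA, scenarios, PSA sampling and acceptability curves."""

import numpy as np
import pandas as pd
import pytest

from nsclc_cea.markov import run_all
from nsclc_cea.params import DistributionSpec, ParamValue, iter_params
from nsclc_cea.sensitivity import (
    PSASample,
    ceac,
    one_way,
    psa_to_frame,
    run_psa,
    run_scenario,
    sample_params,
    scenario_inputs,
    tornado,
)


class TestOneWay:
    def test_zero_width_range_leaves_icer_unchanged(self, small_inputs):
        inputs = small_inputs.copy()
        pv = inputs.management_costs["pf_per_week"]
        pv.low = pv.high = pv.base
        lo, hi = one_way(inputs, "management_costs.pf_per_week",
                         ("tki_1", "reference_chemo"))
        assert lo == pytest.approx(hi, rel=1e-12)

    def test_inputs_left_untouched(self, small_inputs):
        before = {p: pv.base for p, pv in iter_params(small_inputs)}
        one_way(small_inputs, "utilities.u_pf", ("tki_1", "reference_chemo"))
        after = {p: pv.base for p, pv in iter_params(small_inputs)}
        assert before == after

    def test_unknown_parameter_rejected(self, small_inputs):
        with pytest.raises(KeyError):
            one_way(small_inputs, "no.such.param", ("tki_1", "reference_chemo"))

    def test_shared_one_off_cost_shifts_icer_by_cost_difference_only(
        self, small_inputs
    ):
        # terminal care is paid once per death in both arms; a two-run
        # differencing oracle predicts the ICER shift from the cost legs alone
        from nsclc_cea.markov import accrue, build_trace

        def pair(inputs):
            out = {}
            for name in ("tki_1", "reference_chemo"):
                arm = inputs.arm(name)
                out[name] = accrue(build_trace(arm, inputs), arm, inputs)
            return out

        pv = small_inputs.management_costs["terminal_one_off"]
        lo_icer, hi_icer = one_way(
            small_inputs, "management_costs.terminal_one_off",
            ("tki_1", "reference_chemo"),
        )
        for bound, got in ((pv.low, lo_icer), (pv.high, hi_icer)):
            inputs = small_inputs.copy()
            inputs.management_costs["terminal_one_off"].base = bound
            res = pair(inputs)
            dq = res["tki_1"].qaly - res["reference_chemo"].qaly
            dc = res["tki_1"].cost - res["reference_chemo"].cost
            assert got == pytest.approx(dc / dq, rel=1e-12)

    def test_most_influential_parameters_for_combination_vs_chemo(self, uk_inputs):
        table = tornado(uk_inputs, ("gefitinib_pbct", "pfct"))
        top3 = set(table.head(3)["param"])
        assert top3 == {
            "arms[gefitinib_pbct].hrs.pfs_hr",
            "arms[gefitinib_pbct].hrs.os_hr",
            "utilities.u_pf",
        }


class TestScenarios:
    def test_empty_override_set_is_identity(self, uk_inputs, uk_results):
        res = run_scenario(uk_inputs, "base_case")
        for a, b in zip(res, uk_results):
            assert (a.cost, a.qaly) == (b.cost, b.qaly)

    def test_unknown_scenario_rejected(self, uk_inputs):
        with pytest.raises(KeyError):
            run_scenario(uk_inputs, "not_a_scenario")

    @pytest.mark.parametrize("country", ["uk_inputs", "china_inputs"])
    def test_alternative_utilities_raise_every_arms_qalys(self, country, request):
        inputs = request.getfixturevalue(country)
        base = run_all(inputs)
        alt = run_scenario(inputs, "alt_utilities")
        for a, b in zip(alt, base):
            assert a.qaly > b.qaly, a.arm

    def test_updated_osimertinib_survival_raises_its_qalys(self, uk_inputs):
        base = {r.arm: r for r in run_all(uk_inputs)}
        upd = {r.arm: r for r in run_scenario(uk_inputs, "flaura_os_update")}
        assert upd["osimertinib"].qaly > base["osimertinib"].qaly
        assert upd["gefitinib"].qaly == base["gefitinib"].qaly

    def test_t790m_second_line_raises_tki_arm_costs(self, uk_inputs):
        base = {r.arm: r for r in run_all(uk_inputs)}
        t79 = {r.arm: r for r in run_scenario(uk_inputs, "t790m_osimertinib_second_line")}
        for arm in ("gefitinib", "erlotinib", "afatinib", "dacomitinib"):
            assert t79[arm].cost > base[arm].cost, arm
        # chemotherapy pathways unchanged
        assert t79["pfct"].cost == pytest.approx(base["pfct"].cost)

    def test_list_prices_make_reference_chemo_competitive(self, uk_inputs):
        from nsclc_cea.frontier import DOMINATED, build_frontier

        base = {r.arm: r for r in run_all(uk_inputs)}
        bnf = {r.arm: r for r in run_scenario(uk_inputs, "bnf_prices_uk")}
        assert bnf["gefitinib"].cost > base["gefitinib"].cost + 10_000
        front = build_frontier(list(bnf.values()))
        assert front.classifications["pfct"] != DOMINATED

    def test_list_price_scenario_is_uk_only(self, china_inputs):
        with pytest.raises(ValueError):
            scenario_inputs(china_inputs, "bnf_prices_uk")


class TestSampleParams:
    def test_gamma_cost_mean_recovered(self):
        pv = ParamValue(
            base=66.0, dist=DistributionSpec("gamma", {"shape": 96.04, "scale": 0.69})
        )
        rng = np.random.default_rng(0)
        draws = np.array([pv.sample(rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(66.2676, rel=0.02)

    def test_lognormal_hr_median_recovered(self):
        pv = ParamValue(
            base=0.37, dist=DistributionSpec("lognormal", {"mu": -0.99, "sigma": 0.08})
        )
        rng = np.random.default_rng(1)
        draws = np.array([pv.sample(rng) for _ in range(10_000)])
        assert np.median(draws) == pytest.approx(0.371577, rel=0.02)

    def test_degenerate_lognormal_is_constant(self):
        pv = ParamValue(
            base=1.0, dist=DistributionSpec("lognormal", {"mu": 0.0, "sigma": 0.0})
        )
        rng = np.random.default_rng(2)
        assert {pv.sample(rng) for _ in range(10)} == {1.0}

    def test_draws_reproducible_and_originals_untouched(self, small_inputs):
        before = {p: pv.base for p, pv in iter_params(small_inputs)}
        a = sample_params(small_inputs, 99)
        b = sample_params(small_inputs, 99)
        after = {p: pv.base for p, pv in iter_params(small_inputs)}
        assert before == after
        assert {p: pv.base for p, pv in iter_params(a)} == {
            p: pv.base for p, pv in iter_params(b)
        }
        assert (a.pfs_ref.scale, a.pfs_ref.shape) == (b.pfs_ref.scale, b.pfs_ref.shape)
        assert a.pfs_ref.scale != small_inputs.pfs_ref.scale

    def test_weibull_pair_sampled_jointly_with_negative_correlation(self, uk_inputs):
        rng = np.random.default_rng(3)
        logs = np.array(
            [
                [np.log(s.scale), np.log(s.shape)]
                for s in (uk_inputs.pfs_ref.sample(rng) for _ in range(3000))
            ]
        )
        corr = np.corrcoef(logs.T)[0, 1]
        assert corr == pytest.approx(-0.5, abs=0.06)


class TestRunPsa:
    def test_single_iteration_is_one_draw_plus_run(self, small_inputs):
        samples = run_psa(small_inputs, n=1, seed=5)
        assert len(samples) == 1
        seed0 = int(np.random.default_rng(5).integers(0, 2**31 - 1, size=1)[0])
        assert samples[0].seed == seed0
        manual = {r.arm: (r.cost, r.qaly) for r in run_all(sample_params(small_inputs, seed0))}
        assert samples[0].results == manual

    def test_same_seed_bitwise_identical(self, small_inputs):
        a = run_psa(small_inputs, n=5, seed=11)
        b = run_psa(small_inputs, n=5, seed=11)
        assert [s.results for s in a] == [s.results for s in b]

    def test_mean_outcomes_stable_under_more_iterations(self, small_inputs):
        small = psa_to_frame(run_psa(small_inputs, n=60, seed=21))
        large = psa_to_frame(run_psa(small_inputs, n=240, seed=22))
        m_small = small.groupby("arm")[["cost", "qaly"]].mean()
        m_large = large.groupby("arm")[["cost", "qaly"]].mean()
        assert np.allclose(m_small["cost"], m_large["cost"], rtol=0.10)
        assert np.allclose(m_small["qaly"], m_large["qaly"], rtol=0.10)

    def test_invalid_iteration_count_rejected(self, small_inputs):
        with pytest.raises(ValueError):
            run_psa(small_inputs, n=0, seed=1)


class TestCeac:
    def test_single_arm_probability_one_everywhere(self):
        samples = [PSASample(i, i, {"only": (1000.0, 1.0)}) for i in range(5)]
        curve = ceac(samples, [0.0, 10_000.0, 50_000.0])
        assert (curve.probabilities["only"] == 1.0).all()

    def test_zero_threshold_rewards_cheapest(self):
        samples = [
            PSASample(0, 0, {"cheap": (100.0, 0.1), "dear": (200.0, 5.0)}),
            PSASample(1, 1, {"cheap": (150.0, 0.1), "dear": (500.0, 5.0)}),
        ]
        curve = ceac(samples, [0.0])
        assert curve.probabilities.loc[0.0, "cheap"] == 1.0

    def test_crossover_at_the_icer_between_two_point_clouds(self):
        # deterministic clouds: ICER between the arms is exactly 1000/QALY
        samples = [
            PSASample(i, i, {"a": (1000.0, 1.0), "b": (2000.0, 2.0)})
            for i in range(4)
        ]
        curve = ceac(samples, [500.0, 999.0, 1001.0, 2000.0])
        assert curve.probabilities.loc[500.0, "a"] == 1.0
        assert curve.probabilities.loc[999.0, "a"] == 1.0
        assert curve.probabilities.loc[1001.0, "b"] == 1.0
        # exactly at the ICER both tie and split equally
        tie = ceac(samples, [1000.0]).probabilities
        assert tie.loc[1000.0, "a"] == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, small_inputs):
        samples = run_psa(small_inputs, n=40, seed=8)
        curve = ceac(samples, np.linspace(0.0, 100_000.0, 11))
        sums = curve.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert ((curve.probabilities >= 0) & (curve.probabilities <= 1)).all().all()

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac([], [0.0])
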