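"""One-way, probabilistic and scenario sensitivity analyses."""

import numpy as np
import pytest

from psmcea.config import apply_overrides, strategy_economics
from psmcea.economics import cost_breakdown
from psmcea.engine import occupancy_trace
from psmcea.pipeline import evaluate_arms
from psmcea.sensitivity import (OneWayRange, PSASpec, beta_moments,
                                default_one_way_ranges, draw_psa_inputs,
                                gamma_moments, one_way, run_psa,
                                run_scenarios)

WTP = 37654.0


class TestMomentMatching:
    def test_gamma_mean_100_sd_20(self):
        assert gamma_moments(100.0, 20.0) == pytest.approx((25.0, 4.0))

    def test_beta_mean_08_sd_005(self):
        a, b = beta_moments(0.8, 0.05)
        assert a + b == pytest.approx(63.0)
        assert a == pytest.approx(50.4)

    def test_beta_rejects_mean_at_or_above_one(self):
        with pytest.raises(ValueError):
            beta_moments(1.0, 0.05)

    def test_draw_means_recover_base_values(self):
        ranges = [
            OneWayRange("costs_usd.bsc_per_cycle", 200.0, 160.0, 240.0),
            OneWayRange("utilities.pfs", 0.8, 0.72, 0.88),
            OneWayRange("population.bsa", 1.67, 1.40, 1.94),
        ]
        spec = PSASpec(n_iterations=100_000, seed=5)
        draws = draw_psa_inputs(spec, ranges)
        arr = {p: np.array([d[p] for d in draws]) for p in draws[0]}
        assert np.mean(arr["costs_usd.bsc_per_cycle"]) == pytest.approx(
            200.0, rel=5e-3)
        assert np.mean(arr["utilities.pfs"]) == pytest.approx(0.8, rel=5e-3)
        assert np.mean(arr["population.bsa"]) == pytest.approx(1.67, rel=5e-3)
        assert arr["population.bsa"].min() >= 1.40
        assert arr["population.bsa"].max() <= 1.94

    def test_draws_seed_reproducible(self):
        ranges = [OneWayRange("utilities.pfs", 0.8, 0.72, 0.88)]
        a = draw_psa_inputs(PSASpec(n_iterations=50, seed=3), ranges)
        b = draw_psa_inputs(PSASpec(n_iterations=50, seed=3), ranges)
        assert a == b


class TestOneWay:
    def test_ignored_parameter_has_zero_span_sorted_last(self, evaluator):
        ranges = [
            OneWayRange("utilities.pfs", 0.804, 0.7236, 0.8844),
            # docetaxel price is unused while BSC is the second-line mix
            OneWayRange("prices_usd_per_mg.docetaxel", 0.22, 0.176, 0.264),
        ]
        table = one_way(ranges, evaluator, WTP)
        last = table.iloc[-1]
        assert last["parameter"] == "prices_usd_per_mg.docetaxel"
        assert last["span"] == 0.0

    def test_pfs_utility_monotone_effect_on_icer(self, evaluator):
        """TC gains more PFS time, so a lower PFS utility worsens (raises)
        the ICER."""
        table = one_way([OneWayRange("utilities.pfs", 0.804, 0.7236, 0.8844)],
                        evaluator, WTP)
        assert table.loc[0, "icer_low"] > table.loc[0, "icer_high"]

    def test_row_order_invariant_to_input_order(self, cfg, evaluator):
        ranges = default_one_way_ranges(cfg)
        fwd = one_way(ranges, evaluator, WTP)
        rev = one_way(list(reversed(ranges)), evaluator, WTP)
        assert list(fwd["parameter"]) == list(rev["parameter"])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            OneWayRange("x", 1.0, 2.0, 3.0)


class TestPSA:
    def test_degenerate_zero_variance_is_base_case_step(self, cfg, evaluator,
                                                        best_fits):
        base = evaluate_arms(cfg, best_fits)
        ranges = [OneWayRange("utilities.pfs", 0.804, 0.804, 0.804)]
        out = run_psa(PSASpec(n_iterations=1000, seed=1), evaluator, ranges,
                      WTP)
        assert out.n == 1000 and out.n_failed == 0
        assert np.all(out.delta_costs == base.delta_cost)
        assert np.all(out.delta_effects == base.delta_effect)
        ceac = out.ceac_frame()
        expected = (ceac["wtp"] * base.delta_effect - base.delta_cost
                    > 0).astype(float)
        np.testing.assert_array_equal(ceac["p_comparator"], expected)

    def test_two_strategy_ceac_sums_to_one(self, cfg, evaluator):
        ranges = default_one_way_ranges(cfg)
        out = run_psa(PSASpec(n_iterations=200, seed=2), evaluator, ranges,
                      WTP)
        ceac = out.ceac_frame()
        np.testing.assert_allclose(ceac["p_comparator"] + ceac["p_reference"],
                                   1.0, atol=1e-15)
        assert ceac["p_comparator"].between(0, 1).all()

    def test_ceac_estimator_convergence(self, cfg, evaluator):
        """The 1000-draw CEAC point lies inside the binomial 99% CI of a
        much larger run at the same threshold."""
        from scipy import stats
        ranges = default_one_way_ranges(cfg)
        small = run_psa(PSASpec(n_iterations=1000, seed=11), evaluator,
                        ranges, WTP)
        big = run_psa(PSASpec(n_iterations=8000, seed=12), evaluator, ranges,
                      WTP)
        # pick a threshold where the probability is not saturated
        grid = small.wtp_grid
        p_big = np.array([big.prob_cost_effective(w) for w in grid])
        idx = int(np.argmin(np.abs(p_big - 0.5)))
        w = grid[idx]
        p_hat = small.prob_cost_effective(w)
        lo, hi = stats.binom.interval(0.99, 1000, p_big[idx])
        assert lo / 1000 <= p_hat <= hi / 1000

    def test_failed_iterations_recorded_not_dropped(self, evaluator):
        calls = {"n": 0}

        def flaky(overrides):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("boom")
            return evaluator(overrides)

        ranges = [OneWayRange("utilities.pfs", 0.804, 0.7236, 0.8844)]
        out = run_psa(PSASpec(n_iterations=50, seed=4), flaky, ranges, WTP)
        assert out.n_failed == 10
        assert out.n == 40
        assert len(out.failures) == 10


class TestScenarios:
    def test_empty_delta_reproduces_base_exactly(self, cfg, evaluator,
                                                 best_fits):
        base = evaluate_arms(cfg, best_fits)
        table = run_scenarios(["base"], evaluator)
        assert table.loc[0, "delta_cost"] == base.delta_cost
        assert table.loc[0, "delta_effect"] == base.delta_effect
        assert table.loc[0, "icer"] == base.icer

    def test_horizon_scenarios_extend_qalys(self, evaluator):
        table = run_scenarios(["base", "horizon_20y", "horizon_30y"],
                              evaluator).set_index("scenario")
        for arm in ("reference", "comparator"):
            q = table[f"qalys_{arm}"]
            assert q["base"] <= q["horizon_20y"] <= q["horizon_30y"]

    def test_docetaxel_scenario_touches_only_pd_costs(self, cfg, best_fits):
        """Switching second-line BSC to docetaxel leaves the PFS-state
        cost components bit-identical."""
        from psmcea.config import model_settings
        settings = model_settings(cfg)
        doce_cfg = apply_overrides(cfg, {"second_line.bsc_drug": "docetaxel"})
        for arm in ("TC", "PC"):
            trace = occupancy_trace(best_fits[(arm, "PFS")],
                                    best_fits[(arm, "OS")], settings)
            base_parts = cost_breakdown(trace, strategy_economics(cfg, arm),
                                        settings)
            doce_parts = cost_breakdown(trace,
                                        strategy_economics(doce_cfg, arm),
                                        settings)
            for key in ("first_line_drug", "monitoring", "hospitalization",
                        "hospice", "adverse_events"):
                assert base_parts[key] == doce_parts[key]
            assert base_parts["second_line"] != doce_parts["second_line"]

    def test_unknown_scenario_rejected(self, evaluator):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenarios(["warp_drive"], evaluator)
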