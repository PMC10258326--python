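"""Cost/QALY accrual and incremental cost-effectiveness arithmetic."""

import numpy as np
import pytest

from psmcea.economics import (AdverseEvent, ArmOutcome, StrategyEconomics,
                              accumulate_costs, accumulate_qalys,
                              cost_breakdown, icer, monitoring_schedule,
                              per_cycle_drug_cost, wtp_decision)
from psmcea.engine import ModelSettings, OccupancyTrace

ZERO_PRICES = {d: 0.0 for d in ("toripalimab", "paclitaxel", "carboplatin",
                                "cisplatin", "pemetrexed", "docetaxel")}


def econ_with(**kw):
    defaults = dict(arm="TC", prices_per_mg=dict(ZERO_PRICES))
    defaults.update(kw)
    return StrategyEconomics(**defaults)


def three_cycle_settings():
    # horizon of exactly three 21-day cycles
    return ModelSettings(horizon_years=63.0 / 365.25)


def three_cycle_trace(settings):
    d = settings.cycle_length_months
    return OccupancyTrace(
        times=np.array([0.0, d, 2 * d, 3 * d]),
        pfs=np.array([1.0, 0.8, 0.6, 0.5]),
        pd=np.array([0.0, 0.1, 0.2, 0.2]),
        dead=np.array([0.0, 0.1, 0.2, 0.3]),
        new_deaths=np.array([0.0, 0.1, 0.1, 0.1]))


class TestDrugCosts:
    def test_paclitaxel_dose_is_501mg_at_reference_bsa(self):
        econ = econ_with(prices_per_mg={**ZERO_PRICES, "paclitaxel": 1.0},
                         squamous_fraction=1.0)
        # 100 mg/m2 x 1.67 m2 x 3 administrations = 501 mg per cycle
        assert econ.chemo_cycle_cost == pytest.approx(501.0)

    def test_pemetrexed_dose_is_835mg_at_reference_bsa(self):
        econ = econ_with(prices_per_mg={**ZERO_PRICES, "pemetrexed": 1.0},
                         squamous_fraction=0.0)
        assert econ.chemo_cycle_cost == pytest.approx(835.0)  # 500 x 1.67

    def test_zero_prices_zero_cost(self):
        econ = econ_with()
        assert per_cycle_drug_cost("TC", 1, False, econ) == 0.0
        assert per_cycle_drug_cost("TC", 7, True, econ) == 0.0

    def test_pc_arm_excludes_toripalimab_first_line(self):
        prices = {**ZERO_PRICES, "toripalimab": 1.0}
        tc = econ_with(prices_per_mg=prices)
        pc = econ_with(arm="PC", prices_per_mg=prices,
                       include_toripalimab_first_line=False)
        assert per_cycle_drug_cost("TC", 1, False, tc) == pytest.approx(240.0)
        assert per_cycle_drug_cost("PC", 1, False, pc) == 0.0
        assert pc.maintenance_cycle_cost == 0.0

    def test_negative_price_rejected(self):
        with pytest.raises(ValueError):
            econ_with(prices_per_mg={**ZERO_PRICES, "paclitaxel": -1.0})

    def test_second_line_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            econ_with(second_line_toripalimab=0.5, second_line_bsc=0.4)


class TestAccrual:
    def test_everyone_dead_after_first_cycle_costs_one_hospice(self):
        settings = ModelSettings(horizon_years=63.0 / 365.25)
        d = settings.cycle_length_months
        trace = OccupancyTrace(times=np.array([0.0, d, 2 * d, 3 * d]),
                               pfs=np.array([1.0, 0.0, 0.0, 0.0]),
                               pd=np.zeros(4),
                               dead=np.array([0.0, 1.0, 1.0, 1.0]),
                               new_deaths=np.array([0.0, 1.0, 0.0, 0.0]))
        econ = econ_with(hospice_one_time=1000.0)
        disc_mid1 = 1.05 ** (-(d / 2) / 12.0)
        # residual half-cycle of PFS occupancy carries no cost (all
        # prices zero); only the one-time hospice cost remains
        assert accumulate_costs(trace, econ, settings) == pytest.approx(
            1000.0 * disc_mid1)

    def test_three_cycle_manual_oracle(self):
        """Spreadsheet-style hand computation reproduced to 1e-9."""
        settings = three_cycle_settings()
        trace = three_cycle_trace(settings)
        d = settings.cycle_length_months
        econ = econ_with(
            prices_per_mg={**ZERO_PRICES, "toripalimab": 1.0},
            induction_cycles=2,
            second_line_toripalimab=0.2, second_line_bsc=0.8,
            bsc_cost_per_cycle=50.0, hospice_one_time=1000.0,
            administration_per_cycle=10.0, lab_test_cost=100.0,
            hospitalization_pfs_per_cycle=5.0,
            hospitalization_pd_per_cycle=7.0,
            adverse_events=(AdverseEvent("ae", 0.5, 100.0, 0.01),),
            u_pfs=0.8, u_pd=0.6)

        pfs_avg = np.array([0.9, 0.7, 0.55])
        pd_avg = np.array([0.05, 0.15, 0.20])
        new_deaths = np.array([0.1, 0.1, 0.1])
        disc_c = 1.05 ** (-np.array([d / 2, 3 * d / 2, 5 * d / 2]) / 12.0)
        # toripalimab 240 mg x $1/mg every cycle (induction & maintenance)
        first_line = (240.0 + 10.0) * pfs_avg
        monitoring = 100.0 * np.array([1.0, 0.0, 1.0]) * pfs_avg  # visits at 0, 6w
        hosp = 5.0 * pfs_avg + 7.0 * pd_avg
        second = (0.2 * 240.0 + 0.8 * 50.0) * pd_avg
        hospice = 1000.0 * new_deaths
        ae = np.array([0.5 * 100.0, 0.0, 0.0])
        expected_cost = ((first_line + monitoring + hosp + second + hospice
                          + ae) * disc_c).sum()
        assert accumulate_costs(trace, econ, settings) == pytest.approx(
            expected_cost, abs=1e-9)

        expected_q = ((0.8 * pfs_avg + 0.6 * pd_avg) * d / 12.0
                      * disc_c).sum() - 0.5 * 0.01 * disc_c[0]
        assert accumulate_qalys(trace, econ, settings) == pytest.approx(
            expected_q, abs=1e-9)

    def test_cost_homogeneity_in_prices(self):
        settings = three_cycle_settings()
        trace = three_cycle_trace(settings)
        kw = dict(
            prices_per_mg={**ZERO_PRICES, "toripalimab": 1.7,
                           "paclitaxel": 0.1, "pemetrexed": 0.4},
            bsc_cost_per_cycle=50.0, hospice_one_time=1000.0,
            administration_per_cycle=10.0, lab_test_cost=100.0,
            hospitalization_pfs_per_cycle=5.0,
            hospitalization_pd_per_cycle=7.0,
            second_line_toripalimab=0.2, second_line_bsc=0.8,
            adverse_events=(AdverseEvent("ae", 0.5, 100.0, 0.0),))
        base = accumulate_costs(trace, econ_with(**kw), settings)
        doubled = dict(kw)
        doubled["prices_per_mg"] = {k: 2 * v
                                    for k, v in kw["prices_per_mg"].items()}
        for key in ("bsc_cost_per_cycle", "hospice_one_time",
                    "administration_per_cycle", "lab_test_cost",
                    "hospitalization_pfs_per_cycle",
                    "hospitalization_pd_per_cycle"):
            doubled[key] = 2 * kw[key]
        doubled["adverse_events"] = (AdverseEvent("ae", 0.5, 200.0, 0.0),)
        assert accumulate_costs(trace, econ_with(**doubled),
                                settings) == pytest.approx(2 * base)

    def test_full_utilities_give_life_years(self):
        from psmcea.engine import discounted_life_years
        settings = three_cycle_settings()
        trace = three_cycle_trace(settings)
        econ = econ_with(u_pfs=1.0, u_pd=1.0)
        assert accumulate_qalys(trace, econ, settings) == pytest.approx(
            discounted_life_years(trace, settings), abs=1e-12)

    def test_zero_utilities_give_zero_qalys(self):
        settings = three_cycle_settings()
        trace = three_cycle_trace(settings)
        assert accumulate_qalys(trace, econ_with(u_pfs=0.0, u_pd=0.0),
                                settings) == 0.0

    def test_utility_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            econ_with(u_pfs=1.2)

    def test_cost_nondecreasing_in_induction_cycles(self):
        """With PD-state costs zeroed, more induction cycles never cost
        less (chemotherapy backbone on top of maintenance)."""
        settings = ModelSettings()
        from psmcea.engine import occupancy_trace
        from psmcea.survival import ParametricSurvivalFit
        pfs = ParametricSurvivalFit("lognormal", (np.log(8.3), 0.9), 0, 2, 10)
        osf = ParametricSurvivalFit("lognormal", (np.log(28.0), 0.9), 0, 2, 10)
        trace = occupancy_trace(pfs, osf, settings)
        prices = {**ZERO_PRICES, "toripalimab": 1.7, "paclitaxel": 0.1,
                  "carboplatin": 0.05, "cisplatin": 0.02, "pemetrexed": 0.4}
        prev = 0.0
        for k in (4, 5, 6):
            econ = econ_with(prices_per_mg=prices, induction_cycles=k)
            total = accumulate_costs(trace, econ, settings)
            assert total >= prev
            prev = total

    def test_monitoring_schedule_density_switch(self):
        """6-weekly to month 12, 9-weekly after."""
        visits = monitoring_schedule(24.0)
        gaps = np.diff(visits)
        in_first_year = visits[1:] <= 12.0 + 1e-9
        assert np.allclose(gaps[in_first_year], 42.0 / 30.4375, atol=1e-9)
        assert np.allclose(gaps[~in_first_year], 63.0 / 30.4375, atol=1e-9)


class TestICER:
    def test_ratio_from_printed_style_deltas(self):
        ref = ArmOutcome("PC", 0.0, 0.0)
        comp = ArmOutcome("TC", 18501.0, 0.57)
        res = icer(ref, comp)
        assert res.icer == pytest.approx(18501.0 / 0.57)
        assert round(res.icer) == 32458

    def test_dominance_flags(self):
        dominant = icer(ArmOutcome("PC", 100.0, 1.0),
                        ArmOutcome("TC", 0.0, 1.5))
        assert dominant.dominance == "comparator_dominant"
        assert dominant.icer < 0
        dominated = icer(ArmOutcome("PC", 0.0, 1.5),
                         ArmOutcome("TC", 100.0, 1.0))
        assert dominated.dominance == "comparator_dominated"

    def test_zero_effect_delta_undefined(self):
        res = icer(ArmOutcome("PC", 0.0, 1.0), ArmOutcome("TC", 100.0, 1.0))
        assert not res.icer_defined and res.icer is None

    def test_antisymmetry(self):
        a, b = ArmOutcome("PC", 100.0, 1.0), ArmOutcome("TC", 250.0, 1.4)
        fwd, rev = icer(a, b), icer(b, a)
        assert fwd.delta_cost == -rev.delta_cost
        assert fwd.delta_effect == -rev.delta_effect

    def test_mismatched_settings_rejected(self):
        s1, s2 = ModelSettings(), ModelSettings(horizon_years=20)
        with pytest.raises(ValueError):
            icer(ArmOutcome("PC", 0, 1, s1), ArmOutcome("TC", 1, 2, s2))

    def test_wtp_decisions(self):
        res = icer(ArmOutcome("PC", 0.0, 0.0), ArmOutcome("TC", 18375.0, 0.57))
        assert wtp_decision(res, 37654.0)       # ICER ~32237 < WTP
        assert not wtp_decision(res, 30000.0)
        dominant = icer(ArmOutcome("PC", 100.0, 1.0), ArmOutcome("TC", 0.0, 2.0))
        assert wtp_decision(dominant, 0.0)

    def test_nmb_ordering_agrees_with_decision(self):
        rng = np.random.default_rng(7)
        wtp = 37654.0
        for _ in range(200):
            dc = rng.normal(0, 20000)
            de = rng.normal(0, 0.5)
            if abs(de) < 1e-6:
                continue
            res = icer(ArmOutcome("PC", 0.0, 0.0), ArmOutcome("TC", dc, de))
            assert wtp_decision(res, wtp) == (wtp * de - dc > 0) \
                or wtp * de - dc == 0
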