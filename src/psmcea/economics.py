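"""Cost and QALY accrual over an occupancy trace, and the ICER.

Costing follows the healthcare-system perspective of the underlying
trial-based evaluation: first-line drug acquisition (toripalimab 240 mg
flat per 3-week cycle in the TC arm; histology-weighted chemotherapy
dosed per m^2 of body surface area), administration and hospitalization/
nursing, tumour-surveillance laboratory tests (baseline, then every 6
weeks for 12 months, every 9 weeks thereafter), a second-line mix in the
progressed state (toripalimab monotherapy vs best supportive care, or
docetaxel in a scenario), a one-time hospice cost applied to new deaths,
and a one-time grade-3/4 adverse-event bundle in the first cycle.
Utilities weight progression-free and progressed person-time; death has
utility zero; AE disutilities are one-time decrements in cycle 1.

Doses are mg-exact (no vial rounding).  All cash flows and utilities are
discounted at cycle midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .engine import (MONTHS_PER_YEAR, ModelSettings, OccupancyTrace,
                     half_cycle_time_in_state, midpoint_discount_factors)

__all__ = [
    "AdverseEvent",
    "StrategyEconomics",
    "ArmOutcome",
    "CEResult",
    "per_cycle_drug_cost",
    "monitoring_schedule",
    "accumulate_costs",
    "accumulate_qalys",
    "cost_breakdown",
    "icer",
    "wtp_decision",
]

WEEKS_PER_MONTH = 365.25 / 12.0 / 7.0


@dataclass(frozen=True)
class AdverseEvent:
    """One grade-3/4 adverse event: incidence in this arm, one-time
    management cost (USD) and one-time QALY decrement."""

    name: str
    incidence: float
    unit_cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE {self.name}: incidence must be in [0,1]")
        if self.unit_cost < 0 or self.disutility < 0:
            raise ValueError(f"AE {self.name}: cost/disutility must be >= 0")


@dataclass(frozen=True)
class StrategyEconomics:
    """All cost/utility/schedule inputs for one strategy arm.

    Prices are USD per mg; doses per m^2 scale with ``bsa`` except the
    flat toripalimab dose.  ``second_line_toripalimab`` +
    ``second_line_bsc`` must sum to 1; ``second_line_bsc_drug`` switches
    the supportive-care comparator to a priced drug (e.g. docetaxel
    75 mg/m^2 per cycle) in scenario analyses.
    """

    arm: str
    prices_per_mg: dict[str, float]
    toripalimab_mg_per_cycle: float = 240.0
    include_toripalimab_first_line: bool = True
    bsa: float = 1.67
    squamous_fraction: float = 0.473
    cisplatin_fraction_nonsquamous: float = 0.5
    induction_cycles: int = 6
    # (drug, mg per m^2 per administration, administrations per cycle)
    paclitaxel_dose: tuple[float, int] = (100.0, 3)
    carboplatin_dose: tuple[float, int] = (400.0, 1)
    pemetrexed_dose: tuple[float, int] = (500.0, 1)
    cisplatin_dose: tuple[float, int] = (75.0, 1)
    docetaxel_dose: tuple[float, int] = (75.0, 1)
    second_line_toripalimab: float = 0.0
    second_line_bsc: float = 1.0
    second_line_bsc_drug: str | None = None
    bsc_cost_per_cycle: float = 0.0
    hospice_one_time: float = 0.0
    administration_per_cycle: float = 0.0
    lab_test_cost: float = 0.0
    hospitalization_pfs_per_cycle: float = 0.0
    hospitalization_pd_per_cycle: float = 0.0
    adverse_events: tuple[AdverseEvent, ...] = ()
    u_pfs: float = 0.8
    u_pd: float = 0.5
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.prices_per_mg.values()):
            raise ValueError("unit prices must be non-negative")
        for name in ("bsc_cost_per_cycle", "hospice_one_time",
                     "administration_per_cycle", "lab_test_cost",
                     "hospitalization_pfs_per_cycle",
                     "hospitalization_pd_per_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        sl = self.second_line_toripalimab + self.second_line_bsc
        if abs(sl - 1.0) > 1e-9:
            raise ValueError("second-line fractions must sum to 1")
        if not 0.0 <= self.squamous_fraction <= 1.0:
            raise ValueError("squamous_fraction must be in [0,1]")
        if not 0.0 <= self.cisplatin_fraction_nonsquamous <= 1.0:
            raise ValueError("cisplatin_fraction_nonsquamous must be in [0,1]")
        for u in (self.u_pfs, self.u_pd, self.u_dead):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must be in [0, 1]")
        if self.induction_cycles < 1:
            raise ValueError("induction_cycles must be >= 1")

    def price(self, drug: str) -> float:
        try:
            return self.prices_per_mg[drug]
        except KeyError:
            raise KeyError(f"no unit price configured for {drug!r}") from None

    def _mg(self, dose: tuple[float, int]) -> float:
        per_m2, n_admin = dose
        return per_m2 * self.bsa * n_admin

    @property
    def toripalimab_cycle_cost(self) -> float:
        return self.toripalimab_mg_per_cycle * self.price("toripalimab")

    @property
    def chemo_cycle_cost(self) -> float:
        """Histology-weighted chemotherapy acquisition cost per induction cycle."""
        sq = (self._mg(self.paclitaxel_dose) * self.price("paclitaxel")
              + self._mg(self.carboplatin_dose) * self.price("carboplatin"))
        f_cis = self.cisplatin_fraction_nonsquamous
        platinum = (f_cis * self._mg(self.cisplatin_dose) * self.price("cisplatin")
                    + (1.0 - f_cis) * self._mg(self.carboplatin_dose)
                    * self.price("carboplatin"))
        nonsq = self._mg(self.pemetrexed_dose) * self.price("pemetrexed") + platinum
        return self.squamous_fraction * sq + (1.0 - self.squamous_fraction) * nonsq

    @property
    def maintenance_cycle_cost(self) -> float:
        """Maintenance: toripalimab (TC arm) + pemetrexed for the
        non-squamous fraction (both arms)."""
        cost = (1.0 - self.squamous_fraction) * self._mg(self.pemetrexed_dose) \
            * self.price("pemetrexed")
        if self.include_toripalimab_first_line:
            cost += self.toripalimab_cycle_cost
        return cost

    @property
    def second_line_cycle_cost(self) -> float:
        """Per-cycle cost of the second-line mix applied to PD occupancy."""
        tori = self.second_line_toripalimab * self.toripalimab_cycle_cost
        if self.second_line_bsc_drug is None:
            bsc = self.second_line_bsc * self.bsc_cost_per_cycle
        else:
            dose = getattr(self, f"{self.second_line_bsc_drug}_dose")
            bsc = self.second_line_bsc * self._mg(dose) \
                * self.price(self.second_line_bsc_drug)
        return tori + bsc

    @property
    def ae_cost_bundle(self) -> float:
        return sum(ae.incidence * ae.unit_cost for ae in self.adverse_events)

    @property
    def ae_disutility_bundle(self) -> float:
        return sum(ae.incidence * ae.disutility for ae in self.adverse_events)


def per_cycle_drug_cost(arm: str, cycle_index: int, in_maintenance: bool,
                        econ: StrategyEconomics) -> float:
    """First-line drug acquisition cost for one treatment cycle (USD).

    Induction cycles price toripalimab (TC arm only) plus the
    histology-weighted chemotherapy backbone; maintenance cycles price
    toripalimab (TC) plus pemetrexed for the non-squamous fraction.
    """
    if arm != econ.arm:
        raise ValueError(f"economics configured for arm {econ.arm!r}, not {arm!r}")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    if in_maintenance:
        return econ.maintenance_cycle_cost
    cost = econ.chemo_cycle_cost
    if econ.include_toripalimab_first_line:
        cost += econ.toripalimab_cycle_cost
    return cost


def monitoring_schedule(horizon_months: float) -> np.ndarray:
    """Laboratory-test times (months): baseline, every 6 weeks to month
    12, every 9 weeks thereafter."""
    six = 6.0 / WEEKS_PER_MONTH
    nine = 9.0 / WEEKS_PER_MONTH
    times = [0.0]
    t = 0.0
    while t + six <= 12.0 + 1e-9:
        t += six
        times.append(t)
    while t + nine <= horizon_months + 1e-9:
        t += nine
        times.append(t)
    return np.asarray(times)


def _cycle_arrays(trace: OccupancyTrace, settings: ModelSettings):
    """Per-cycle occupancy weights, widths and cycle-scaling factors."""
    w = np.diff(trace.times)
    scale = w / settings.cycle_length_months  # partial final cycle pro-rated
    if settings.half_cycle_correction:
        pfs = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
        pd_ = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    else:
        pfs = trace.pfs[:-1]
        pd_ = trace.pd[:-1]
    new_deaths = np.diff(trace.dead)
    return pfs, pd_, new_deaths, w, scale


def cost_breakdown(trace: OccupancyTrace, econ: StrategyEconomics,
                   settings: ModelSettings) -> dict[str, float]:
    """Discounted cost components (USD per model cohort member)."""
    pfs, pd_, new_deaths, w, scale = _cycle_arrays(trace, settings)
    disc = midpoint_discount_factors(trace, settings.discount_rate_costs)
    k = np.arange(1, trace.n_cycles + 1)
    in_maint = k > econ.induction_cycles

    drug = np.where(
        in_maint, econ.maintenance_cycle_cost,
        per_cycle_drug_cost(econ.arm, 1, False, econ))
    first_line = (drug + econ.administration_per_cycle) * pfs * scale

    # laboratory tests are discrete visits, charged to the cycle they
    # start; the epsilon pushes a visit on a cycle boundary into the
    # cycle it opens (6-week visits coincide with 3-week boundaries)
    visits = monitoring_schedule(trace.times[-1])
    counts = np.histogram(visits + 1e-9, bins=trace.times)[0].astype(float)
    monitoring = counts * econ.lab_test_cost * pfs

    hosp = (econ.hospitalization_pfs_per_cycle * pfs
            + econ.hospitalization_pd_per_cycle * pd_) * scale
    second_line = econ.second_line_cycle_cost * pd_ * scale
    hospice = econ.hospice_one_time * new_deaths
    ae = np.zeros_like(disc)
    ae[0] = econ.ae_cost_bundle

    out = {
        "first_line_drug": float((first_line * disc).sum()),
        "monitoring": float((monitoring * disc).sum()),
        "hospitalization": float((hosp * disc).sum()),
        "second_line": float((second_line * disc).sum()),
        "hospice": float((hospice * disc).sum()),
        "adverse_events": float((ae * disc).sum()),
    }
    out["total"] = sum(out.values())
    return out


def accumulate_costs(trace: OccupancyTrace, econ: StrategyEconomics,
                     settings: ModelSettings) -> float:
    """Total discounted cost (USD) for one strategy arm."""
    return cost_breakdown(trace, econ, settings)["total"]


def accumulate_qalys(trace: OccupancyTrace, econ: StrategyEconomics,
                     settings: ModelSettings) -> float:
    """Total discounted QALYs: utility-weighted person-time minus the
    one-time adverse-event disutility bundle in cycle 1."""
    tis = half_cycle_time_in_state(trace, settings)
    disc = midpoint_discount_factors(trace, settings.discount_rate_effects)
    q = (econ.u_pfs * tis["pfs"] + econ.u_pd * tis["pd"]) / MONTHS_PER_YEAR
    total = float((q * disc).sum())
    total -= econ.ae_disutility_bundle * disc[0]
    return total


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one strategy arm under fixed settings."""

    arm: str
    cost: float
    qalys: float
    settings: ModelSettings | None = None


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness of comparator vs reference."""

    reference: ArmOutcome
    comparator: ArmOutcome
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str | None  # 'comparator_dominant' | 'comparator_dominated'

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None


def icer(ref: ArmOutcome, comp: ArmOutcome) -> CEResult:
    """Incremental cost, effect and their ratio for comparator vs reference.

    Dominance flags: comparator dominant when it is cheaper and more
    effective; dominated when costlier and less effective.  The ICER is
    undefined (None) when |dE| < 1e-9.
    """
    if ref.settings is not None and comp.settings is not None \
            and ref.settings != comp.settings:
        raise ValueError("arms were computed under different model settings")
    dc = comp.cost - ref.cost
    de = comp.qalys - ref.qalys
    dominance = None
    if de > 0 and dc < 0:
        dominance = "comparator_dominant"
    elif de < 0 and dc > 0:
        dominance = "comparator_dominated"
    ratio = dc / de if abs(de) >= 1e-9 else None
    return CEResult(reference=ref, comparator=comp, delta_cost=dc,
                    delta_effect=de, icer=ratio, dominance=dominance)


def wtp_decision(result: CEResult, wtp: float) -> bool:
    """Is the comparator cost-effective at the willingness-to-pay threshold?

    True when the comparator dominates, and otherwise when its net
    monetary benefit ``wtp * dE - dC`` is non-negative — equivalent, for
    dE > 0, to the familiar rule ICER <= wtp.
    """
    if result.dominance == "comparator_dominant":
        return True
    if result.dominance == "comparator_dominated":
        return False
    if not result.icer_defined:
        return result.delta_cost <= 0.0
    return wtp * result.delta_effect - result.delta_cost >= 0.0
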