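"""Deterministic, probabilistic and scenario sensitivity analyses.

All three work through one *evaluator*: a closure mapping a dict of
dot-path configuration overrides to a :class:`~psmcea.economics.CEResult`
(see :func:`psmcea.pipeline.make_evaluator`).  Survival fits are held
fixed — uncertainty is propagated through the economic inputs, matching
the source evaluation (costs ~ gamma, utilities ~ beta, body surface
area ~ truncated normal; 1000 Monte Carlo iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEResult

__all__ = [
    "OneWayRange",
    "PSASpec",
    "PSAOutput",
    "default_one_way_ranges",
    "one_way",
    "gamma_moments",
    "beta_moments",
    "draw_psa_inputs",
    "run_psa",
    "SCENARIOS",
    "run_scenarios",
]

Evaluator = Callable[[Mapping[str, Any]], CEResult]


@dataclass(frozen=True)
class OneWayRange:
    """Excursion range for one parameter in one-way sensitivity analysis."""

    parameter: str  # dot path into the configuration
    base: float
    low: float
    high: float
    source: str = "custom"  # 'reported 95% CI' | '±10% non-cost' | '±20% cost' | 'custom'

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter}: need low <= base <= high "
                f"({self.low}, {self.base}, {self.high})")


def _pm(parameter: str, base: float, frac: float, source: str) -> OneWayRange:
    return OneWayRange(parameter, base, base * (1 - frac), base * (1 + frac),
                       source)


def default_one_way_ranges(cfg: dict) -> list[OneWayRange]:
    """Standard ranges: ±20% on costs, ±10% on utilities, the reported
    BSA limits, 0–8% on the discount rate, and a ±36% band on the
    toripalimab price (pending price renegotiation)."""
    ranges: list[OneWayRange] = []
    for drug, price in cfg["prices_usd_per_mg"].items():
        if drug == "toripalimab":
            ranges.append(_pm(f"prices_usd_per_mg.{drug}", price, 0.36, "custom"))
        else:
            ranges.append(_pm(f"prices_usd_per_mg.{drug}", price, 0.20,
                              "±20% cost"))
    for key, value in cfg["costs_usd"].items():
        ranges.append(_pm(f"costs_usd.{key}", value, 0.20, "±20% cost"))
    for i, ae in enumerate(cfg.get("adverse_events", [])):
        ranges.append(_pm(f"adverse_events.{i}.cost_usd", ae["cost_usd"],
                          0.20, "±20% cost"))
        ranges.append(_pm(f"adverse_events.{i}.disutility", ae["disutility"],
                          0.10, "±10% non-cost"))
    for key in ("pfs", "pd"):
        ranges.append(_pm(f"utilities.{key}", cfg["utilities"][key], 0.10,
                          "±10% non-cost"))
    pop = cfg["population"]
    ranges.append(OneWayRange("population.bsa", pop["bsa"], pop["bsa_low"],
                              pop["bsa_high"], "reported 95% CI"))
    ranges.append(OneWayRange("model.discount_rate",
                              cfg["model"]["discount_rate_costs"],
                              0.0, 0.08, "custom"))
    return ranges


def one_way(ranges: Sequence[OneWayRange], evaluate: Evaluator,
            wtp: float) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high excursion.

    Rows are sorted by descending ICER span (ties broken by parameter
    name, so the ordering is invariant to the order ranges are supplied);
    ``crosses_wtp`` marks excursions that push the ICER past the
    threshold or flip its sign.
    """
    rows = []
    for r in ranges:
        res_low = evaluate({r.parameter: r.low})
        res_high = evaluate({r.parameter: r.high})
        icer_low = res_low.icer if res_low.icer_defined else np.nan
        icer_high = res_high.icer if res_high.icer_defined else np.nan
        span = abs(icer_high - icer_low)
        if np.isnan(icer_low) or np.isnan(icer_high):
            crosses = True  # a dominance flip counts as crossing
        else:
            lo, hi = sorted((icer_low, icer_high))
            crosses = bool(lo <= wtp <= hi)
        rows.append({
            "parameter": r.parameter, "source": r.source, "base": r.base,
            "low": r.low, "high": r.high, "icer_low": icer_low,
            "icer_high": icer_high, "span": span, "crosses_wtp": crosses,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["span", "parameter"], ascending=[False, True],
                          na_position="last").reset_index(drop=True)


@dataclass(frozen=True)
class PSASpec:
    """Probabilistic sensitivity analysis settings."""

    n_iterations: int = 1000
    seed: int = 0
    wtp_grid: np.ndarray | None = None  # default: 0 .. 2*WTP in 200 steps

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard deviation."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    return (mean / sd) ** 2, sd * sd / mean


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean in (0,1) and an sd."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must be in (0, 1)")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0:
        raise ValueError("sd too large for a beta distribution")
    return mean * nu, (1.0 - mean) * nu


def _psa_class(path: str) -> str | None:
    """Distribution class for a parameter path; None = held fixed."""
    if path == "population.bsa":
        return "normal"
    if path.startswith(("prices_usd_per_mg.", "costs_usd.")) \
            or path.endswith(".cost_usd"):
        return "gamma"
    if path.startswith("utilities.") or path.endswith(".disutility"):
        return "beta"
    return None


def draw_psa_inputs(spec: PSASpec, ranges: Sequence[OneWayRange],
                    bsa_limits: tuple[float, float] = (1.40, 1.94)
                    ) -> list[dict[str, float]]:
    """Per-iteration override dicts for the PSA.

    Each varied parameter's distribution is moment-matched to
    ``mean = base`` and ``sd = (high - low) / (2 * 1.96)`` from its
    one-way range: gamma for costs, beta for utilities, and a normal
    truncated at the reported limits for body surface area.  Parameters
    with no distribution class (e.g. second-line allocation, discount
    rate) are held fixed.  Same spec (incl. seed) -> identical draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    draws: dict[str, np.ndarray] = {}
    for r in ranges:
        cls = _psa_class(r.parameter)
        sd = (r.high - r.low) / (2.0 * 1.96)
        if cls is None or sd == 0.0 or r.base == 0.0:
            continue
        if cls == "gamma":
            shape, scale = gamma_moments(r.base, sd)
            draws[r.parameter] = rng.gamma(shape, scale, size=n)
        elif cls == "beta":
            a, b = beta_moments(r.base, sd)
            draws[r.parameter] = rng.beta(a, b, size=n)
        elif cls == "normal":
            lo, hi = bsa_limits
            a, b = (lo - r.base) / sd, (hi - r.base) / sd
            dist = stats.truncnorm(a, b, loc=r.base, scale=sd)
            draws[r.parameter] = dist.rvs(size=n, random_state=rng)
    return [{path: float(vals[i]) for path, vals in draws.items()}
            for i in range(n)]


@dataclass
class PSAOutput:
    """Per-iteration incremental outcomes and derived CEAC/scatter views."""

    delta_costs: np.ndarray
    delta_effects: np.ndarray
    wtp_grid: np.ndarray
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.delta_costs.size)

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations where the comparator's net monetary
        benefit is positive at this threshold."""
        return float(np.mean(wtp * self.delta_effects - self.delta_costs > 0))

    def ceac_frame(self) -> pd.DataFrame:
        p = np.array([self.prob_cost_effective(w) for w in self.wtp_grid])
        return pd.DataFrame({"wtp": self.wtp_grid, "p_comparator": p,
                             "p_reference": 1.0 - p})

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.n + 1),
            "delta_cost": self.delta_costs,
            "delta_effect": self.delta_effects,
        })


def run_psa(spec: PSASpec, evaluate: Evaluator,
            ranges: Sequence[OneWayRange], wtp: float,
            bsa_limits: tuple[float, float] = (1.40, 1.94)) -> PSAOutput:
    """Monte Carlo propagation of input uncertainty through the model.

    Iterations whose evaluation fails are recorded and excluded (with a
    count), never silently dropped.
    """
    grid = spec.wtp_grid if spec.wtp_grid is not None \
        else np.linspace(0.0, 2.0 * wtp, 201)
    overrides = draw_psa_inputs(spec, ranges, bsa_limits)
    dc, de, failures = [], [], []
    for i, ov in enumerate(overrides):
        try:
            res = evaluate(ov)
        except Exception as exc:  # noqa: BLE001 - per-iteration isolation
            failures.append(f"iteration {i + 1}: {exc}")
            continue
        dc.append(res.delta_cost)
        de.append(res.delta_effect)
    return PSAOutput(delta_costs=np.asarray(dc), delta_effects=np.asarray(de),
                     wtp_grid=np.asarray(grid, dtype=float),
                     n_failed=len(failures), failures=failures)


SCENARIOS: dict[str, dict[str, Any]] = {
    "base": {},
    "horizon_20y": {"model.horizon_years": 20.0},
    "horizon_30y": {"model.horizon_years": 30.0},
    "docetaxel_second_line": {"second_line.bsc_drug": "docetaxel"},
}


def run_scenarios(scenarios: Iterable[str | tuple[str, dict[str, Any]]],
                  evaluate: Evaluator) -> pd.DataFrame:
    """Re-run the pipeline under named scenario deltas.

    ``scenarios`` mixes built-in ids (see :data:`SCENARIOS`) and
    ``(name, overrides)`` pairs for custom deltas; an empty delta
    reproduces the base case exactly.
    """
    rows = []
    for sc in scenarios:
        if isinstance(sc, str):
            if sc not in SCENARIOS:
                raise ValueError(f"unknown scenario {sc!r}; "
                                 f"known: {sorted(SCENARIOS)}")
            name, overrides = sc, SCENARIOS[sc]
        else:
            name, overrides = sc
        res = evaluate(overrides)
        rows.append({
            "scenario": name,
            "cost_reference": res.reference.cost,
            "qalys_reference": res.reference.qalys,
            "cost_comparator": res.comparator.cost,
            "qalys_comparator": res.comparator.qalys,
            "delta_cost": res.delta_cost,
            "delta_effect": res.delta_effect,
            "icer": res.icer if res.icer_defined else np.nan,
            "dominance": res.dominance or "",
        })
    return pd.DataFrame(rows)
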