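"""Configuration loading, validation and typed-input construction.

The model is driven by one nested mapping (YAML or JSON on disk).  A
packaged default ships with clearly flagged placeholder values for the
cost/utility inputs that are not published in the open-access evidence
base; :func:`validate_config` reports those as warnings and genuine
schema violations as errors, each with its key path.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml

from .economics import AdverseEvent, StrategyEconomics
from .engine import ModelSettings
from .ipd import SyntheticTrialSpec

__all__ = [
    "ValidationIssue",
    "default_config",
    "load_config",
    "validate_config",
    "deep_get",
    "deep_set",
    "config_hash",
    "model_settings",
    "trial_spec",
    "strategy_economics",
    "apply_overrides",
]


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # 'error' | 'warning'
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.level}: {self.path}: {self.message}"


def default_config() -> dict:
    """A deep copy of the packaged default configuration."""
    text = resources.files("psmcea.data").joinpath("default_config.yaml") \
        .read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load YAML/JSON config from ``path``, or the packaged default."""
    if path is None:
        return default_config()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def deep_get(cfg: dict, path: str) -> Any:
    node: Any = cfg
    for part in path.split("."):
        if isinstance(node, list):
            node = node[int(part)]
        else:
            node = node[part]
    return node


def deep_set(cfg: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node: Any = cfg
    for part in parts[:-1]:
        node = node[int(part)] if isinstance(node, list) else node[part]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


def apply_overrides(cfg: dict, overrides: dict[str, Any]) -> dict:
    """Deep-copied config with dot-path overrides applied.

    The pseudo-path ``model.discount_rate`` sets both the cost and the
    effect discount rates (they are varied jointly in sensitivity
    analysis, as in the source evaluation).
    """
    out = copy.deepcopy(cfg)
    for path, value in overrides.items():
        if path == "model.discount_rate":
            deep_set(out, "model.discount_rate_costs", value)
            deep_set(out, "model.discount_rate_effects", value)
        else:
            deep_set(out, path, value)
    return out


def config_hash(cfg: dict) -> str:
    """Stable sha256 of the canonicalized configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _check(cond: bool, issues: list, path: str, msg: str) -> None:
    if not cond:
        issues.append(ValidationIssue("error", path, msg))


def validate_config(cfg: dict) -> list[ValidationIssue]:
    """Schema validation; errors for violations, warnings for placeholders."""
    issues: list[ValidationIssue] = []
    try:
        model = cfg["model"]
        _check(model["cycle_length_days"] > 0, issues,
               "model.cycle_length_days", "must be positive")
        _check(model["horizon_years"] > 0, issues,
               "model.horizon_years", "must be positive")
        for key in ("discount_rate_costs", "discount_rate_effects"):
            _check(0.0 <= model[key] <= 0.2, issues, f"model.{key}",
                   "must be in [0, 0.2]")
        _check(model["wtp"] > 0, issues, "model.wtp", "must be positive")

        util = cfg["utilities"]
        for key in ("pfs", "pd"):
            _check(0.0 <= util[key] <= 1.0, issues, f"utilities.{key}",
                   "utility must be in [0, 1]")

        pop = cfg["population"]
        _check(0.0 < pop["bsa"], issues, "population.bsa", "must be positive")
        _check(pop["bsa_low"] <= pop["bsa"] <= pop["bsa_high"], issues,
               "population.bsa", "must lie within [bsa_low, bsa_high]")
        _check(0.0 <= pop["squamous_fraction"] <= 1.0, issues,
               "population.squamous_fraction", "must be in [0, 1]")

        for drug, price in cfg["prices_usd_per_mg"].items():
            _check(price >= 0, issues, f"prices_usd_per_mg.{drug}",
                   "price must be non-negative")
        for key, value in cfg["costs_usd"].items():
            _check(value >= 0, issues, f"costs_usd.{key}",
                   "cost must be non-negative")

        for arm in ("TC", "PC"):
            mix = cfg["second_line"][arm]
            total = sum(mix.values())
            _check(abs(total - 1.0) <= 1e-9, issues, f"second_line.{arm}",
                   f"fractions must sum to 1 (got {total})")
            for name, frac in mix.items():
                _check(0.0 <= frac <= 1.0, issues,
                       f"second_line.{arm}.{name}", "fraction must be in [0,1]")

        for i, ae in enumerate(cfg.get("adverse_events", [])):
            for arm in ("TC", "PC"):
                _check(0.0 <= ae["incidence"][arm] <= 1.0, issues,
                       f"adverse_events.{i}.incidence.{arm}",
                       "incidence must be in [0, 1]")
            _check(ae["cost_usd"] >= 0, issues,
                   f"adverse_events.{i}.cost_usd", "must be non-negative")
            _check(ae["disutility"] >= 0, issues,
                   f"adverse_events.{i}.disutility", "must be non-negative")

        trial = cfg["trial"]
        for key in ("pfs_median_tc", "pfs_median_pc", "os_median_tc",
                    "os_median_pc", "followup_median"):
            _check(trial[key] > 0, issues, f"trial.{key}", "must be positive")
        _check(trial["n_total"] >= 10, issues, "trial.n_total", "must be >= 10")
    except (KeyError, TypeError) as exc:
        issues.append(ValidationIssue("error", "<schema>",
                                      f"missing or malformed section: {exc}"))

    for path in cfg.get("placeholder_parameters", []):
        issues.append(ValidationIssue(
            "warning", path,
            "placeholder value - replace with a sourced estimate before use"))
    return issues


def model_settings(cfg: dict) -> ModelSettings:
    m = cfg["model"]
    return ModelSettings(
        cycle_length_days=float(m["cycle_length_days"]),
        horizon_years=float(m["horizon_years"]),
        discount_rate_costs=float(m["discount_rate_costs"]),
        discount_rate_effects=float(m["discount_rate_effects"]),
        half_cycle_correction=bool(m["half_cycle_correction"]),
    )


def trial_spec(cfg: dict, seed: int = 0) -> SyntheticTrialSpec:
    t = cfg["trial"]
    return SyntheticTrialSpec(
        n_total=int(t["n_total"]),
        allocation_ratio=tuple(t["allocation"]),
        pfs_median_tc=float(t["pfs_median_tc"]),
        pfs_median_pc=float(t["pfs_median_pc"]),
        os_median_tc=float(t["os_median_tc"]),
        os_median_pc=float(t["os_median_pc"]),
        log_sd_pfs=float(t["log_sd_pfs"]),
        log_sd_os=float(t["log_sd_os"]),
        followup_median=float(t["followup_median"]),
        copula_rho=float(t["copula_rho"]),
        seed=seed,
    )


def _dose(cfg: dict, drug: str) -> tuple[float, int]:
    d = cfg["treatment"]["doses_mg_per_m2"][drug]
    return (float(d[0]), int(d[1]))


def strategy_economics(cfg: dict, arm: str) -> StrategyEconomics:
    """Build the typed per-arm economic inputs from the configuration."""
    if arm not in ("TC", "PC"):
        raise ValueError("arm must be 'TC' or 'PC'")
    costs = cfg["costs_usd"]
    pop = cfg["population"]
    sl = cfg["second_line"][arm]
    aes = tuple(
        AdverseEvent(name=ae["name"], incidence=float(ae["incidence"][arm]),
                     unit_cost=float(ae["cost_usd"]),
                     disutility=float(ae["disutility"]))
        for ae in cfg.get("adverse_events", []))
    return StrategyEconomics(
        arm=arm,
        prices_per_mg={k: float(v) for k, v in cfg["prices_usd_per_mg"].items()},
        toripalimab_mg_per_cycle=float(cfg["treatment"]["toripalimab_mg_per_cycle"]),
        include_toripalimab_first_line=(arm == "TC"),
        bsa=float(pop["bsa"]),
        squamous_fraction=float(pop["squamous_fraction"]),
        cisplatin_fraction_nonsquamous=float(pop["cisplatin_fraction_nonsquamous"]),
        induction_cycles=int(cfg["treatment"]["induction_cycles"]),
        paclitaxel_dose=_dose(cfg, "paclitaxel"),
        carboplatin_dose=_dose(cfg, "carboplatin"),
        pemetrexed_dose=_dose(cfg, "pemetrexed"),
        cisplatin_dose=_dose(cfg, "cisplatin"),
        docetaxel_dose=_dose(cfg, "docetaxel"),
        second_line_toripalimab=float(sl["toripalimab"]),
        second_line_bsc=float(sl["bsc"]),
        second_line_bsc_drug=cfg["second_line"].get("bsc_drug"),
        bsc_cost_per_cycle=float(costs["bsc_per_cycle"]),
        hospice_one_time=float(costs["hospice_one_time"]),
        administration_per_cycle=float(costs["administration_per_cycle"]),
        lab_test_cost=float(costs["laboratory_test"]),
        hospitalization_pfs_per_cycle=float(costs["hospitalization_per_cycle_pfs"]),
        hospitalization_pd_per_cycle=float(costs["hospitalization_per_cycle_pd"]),
        adverse_events=aes,
        u_pfs=float(cfg["utilities"]["pfs"]),
        u_pd=float(cfg["utilities"]["pd"]),
    )
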