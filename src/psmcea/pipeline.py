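"""End-to-end orchestration: data -> fits -> trace -> economics -> analyses.

A run is fully determined by (configuration, seed).  One master
``SeedSequence`` is spawned into per-stage child seeds so stages are
individually reproducible; every run writes into a fresh versioned
subdirectory (``run_0001``, ``run_0002``, ...) together with a manifest
recording the config hash, seed, package version and sha256 checksums of
every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import (apply_overrides, config_hash, model_settings,
                     strategy_economics, trial_spec, validate_config)
from .economics import ArmOutcome, CEResult, accumulate_costs, \
    accumulate_qalys, icer
from .engine import occupancy_trace
from .ipd import ARMS, ENDPOINTS, DigitizedCurve, PseudoIPD, \
    generate_synthetic_trial, reconstruct_ipd
from .sensitivity import PSASpec, default_one_way_ranges, one_way, run_psa, \
    run_scenarios
from .survival import ParametricSurvivalFit, fit_all, model_table, select_best

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "build_ipd",
    "fit_endpoints",
    "evaluate_arms",
    "make_evaluator",
    "run_pipeline",
]

MODES = ("base", "oneway", "psa", "scenarios", "all")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    mode: str
    version: str = __version__
    created: str = ""
    selected_families: dict[str, str] = field(default_factory=dict)
    input_files: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    out_dir: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_ipd(cfg: dict, seed: int) -> dict[tuple[str, str], PseudoIPD]:
    """Reconstruct pseudo-IPD from digitized curves when all four files
    are configured; otherwise generate the synthetic trial."""
    curves_cfg = cfg.get("digitized_curves") or {}
    paths = {(arm, ep): (curves_cfg.get(arm) or {}).get(ep)
             for arm in ARMS for ep in ENDPOINTS}
    if all(paths.values()):
        spec = trial_spec(cfg, seed)
        sizes = spec.arm_sizes
        out = {}
        for (arm, ep), p in paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"digitized curve file missing: {p}")
            curve = DigitizedCurve.from_csv(p, endpoint=ep, arm=arm,
                                            n_at_risk_start=sizes[arm])
            out[(arm, ep)] = reconstruct_ipd(curve, spec.followup_median)
        return out
    if any(paths.values()):
        missing = [f"{a}/{e}" for (a, e), p in paths.items() if not p]
        raise ValueError(f"digitized_curves incomplete; missing {missing}")
    return generate_synthetic_trial(trial_spec(cfg, seed))


def fit_endpoints(ipd: Mapping[tuple[str, str], PseudoIPD],
                  criterion: str = "aic"
                  ) -> tuple[dict[tuple[str, str], ParametricSurvivalFit],
                             dict[tuple[str, str], pd.DataFrame]]:
    """Fit all six families per arm/endpoint and select the best."""
    best, tables = {}, {}
    for key, data in ipd.items():
        fits = fit_all(data)
        best[key] = select_best(fits, criterion)
        tables[key] = model_table(fits)
    return best, tables


def evaluate_arms(cfg: dict,
                  fits: Mapping[tuple[str, str], ParametricSurvivalFit]
                  ) -> CEResult:
    """Traces + economics for both arms under one configuration; PC is
    the reference strategy, TC the comparator."""
    settings = model_settings(cfg)
    outcomes = {}
    for arm in ARMS:
        trace = occupancy_trace(fits[(arm, "PFS")], fits[(arm, "OS")], settings)
        econ = strategy_economics(cfg, arm)
        outcomes[arm] = ArmOutcome(
            arm=arm,
            cost=accumulate_costs(trace, econ, settings),
            qalys=accumulate_qalys(trace, econ, settings),
            settings=settings)
    return icer(ref=outcomes["PC"], comp=outcomes["TC"])


def make_evaluator(cfg: dict,
                   fits: Mapping[tuple[str, str], ParametricSurvivalFit]):
    """Closure mapping config overrides -> CEResult with fits held fixed."""

    def evaluate(overrides: Mapping[str, Any]) -> CEResult:
        return evaluate_arms(apply_overrides(cfg, dict(overrides)), fits)

    return evaluate


def _next_run_dir(out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 1
    while (out_dir / f"run_{n:04d}").exists():
        n += 1
    run_dir = out_dir / f"run_{n:04d}"
    run_dir.mkdir()
    return run_dir


def _base_case_table(result: CEResult) -> pd.DataFrame:
    ref, comp = result.reference, result.comparator
    return pd.DataFrame([
        {"arm": ref.arm, "cost_usd": ref.cost, "qalys": ref.qalys,
         "incr_cost_usd": np.nan, "incr_qalys": np.nan, "icer_usd_per_qaly": np.nan},
        {"arm": comp.arm, "cost_usd": comp.cost, "qalys": comp.qalys,
         "incr_cost_usd": result.delta_cost, "incr_qalys": result.delta_effect,
         "icer_usd_per_qaly": result.icer if result.icer_defined else np.nan},
    ])


def run_pipeline(cfg: dict, mode: str = "base", seed: int = 0,
                 out_dir: str | Path = "results") -> RunManifest:
    """Execute the requested analyses and write CSV/JSON outputs.

    Stages: IPD (reconstruct or generate, seeded) -> six-family fits and
    AIC selection per arm/endpoint -> occupancy traces -> base-case
    economics -> one-way / PSA / scenario analyses per ``mode``.
    Configuration errors abort before any computation.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    issues = validate_config(cfg)
    errors = [i for i in issues if i.level == "error"]
    if errors:
        raise ValueError("invalid configuration:\n"
                         + "\n".join(str(e) for e in errors))
    for issue in issues:
        logger.warning("%s", issue)

    master = np.random.SeedSequence(seed)
    ipd_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    psa_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    run_dir = _next_run_dir(Path(out_dir))
    manifest = RunManifest(config_hash=config_hash(cfg), seed=seed, mode=mode,
                           created=datetime.now(timezone.utc).isoformat(),
                           out_dir=str(run_dir))

    logger.info("stage: pseudo-IPD (seed %d)", ipd_seed)
    ipd = build_ipd(cfg, ipd_seed)
    for (arm, ep), data in ipd.items():
        p = run_dir / f"ipd_{arm}_{ep}.csv"
        data.to_csv(p)

    logger.info("stage: survival fitting and selection")
    criterion = cfg["model"].get("selection_criterion", "aic")
    fits, tables = fit_endpoints(ipd, criterion)
    for (arm, ep), table in tables.items():
        table.to_csv(run_dir / f"model_comparison_{arm}_{ep}.csv", index=False)
    manifest.selected_families = {f"{a}/{e}": fits[(a, e)].family
                                  for a, e in fits}
    (run_dir / "selected_fits.json").write_text(json.dumps(
        {f"{a}/{e}": {"family": f.family, "params": list(f.params),
                      "loglik": f.loglik, "aic": f.aic, "bic": f.bic}
         for (a, e), f in fits.items()}, indent=2))

    logger.info("stage: occupancy traces and base-case economics")
    settings = model_settings(cfg)
    for arm in ARMS:
        trace = occupancy_trace(fits[(arm, "PFS")], fits[(arm, "OS")], settings)
        trace.to_frame(settings).to_csv(run_dir / f"trace_{arm}.csv", index=False)
    base = evaluate_arms(cfg, fits)
    _base_case_table(base).to_csv(run_dir / "base_case.csv", index=False)

    evaluate = make_evaluator(cfg, fits)
    wtp = float(cfg["model"]["wtp"])
    if mode in ("oneway", "all"):
        logger.info("stage: one-way sensitivity analysis")
        tornado = one_way(default_one_way_ranges(cfg), evaluate, wtp)
        tornado.to_csv(run_dir / "tornado.csv", index=False)
    if mode in ("psa", "all"):
        logger.info("stage: probabilistic sensitivity analysis (seed %d)",
                    psa_seed)
        spec = PSASpec(n_iterations=int(cfg["model"].get("psa_iterations", 1000)),
                       seed=psa_seed)
        psa = run_psa(spec, evaluate, default_one_way_ranges(cfg), wtp,
                      bsa_limits=(cfg["population"]["bsa_low"],
                                  cfg["population"]["bsa_high"]))
        psa.scatter_frame().to_csv(run_dir / "psa_draws.csv", index=False)
        psa.ceac_frame().to_csv(run_dir / "ceac.csv", index=False)
        if psa.n_failed:
            logger.warning("PSA: %d failed iterations", psa.n_failed)
    if mode in ("scenarios", "all"):
        logger.info("stage: scenario analyses")
        table = run_scenarios(["base", "horizon_20y", "horizon_30y",
                               "docetaxel_second_line"], evaluate)
        table.to_csv(run_dir / "scenarios.csv", index=False)

    for p in sorted(run_dir.iterdir()):
        if p.name != "manifest.json":
            manifest.outputs[p.name] = _sha256(p)
    (run_dir / "manifest.json").write_text(manifest.to_json())
    logger.info("run complete: %s", run_dir)
    return manifest
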