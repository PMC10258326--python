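# psmcea

Partitioned survival cost-effectiveness modelling of first-line
**toripalimab + chemotherapy (TC) versus chemotherapy alone (PC)** for
advanced non-small cell lung cancer, from the Chinese healthcare-system
perspective. The package is aimed at health-economic modellers who want a
scriptable, testable alternative to spreadsheet implementations of
trial-based partitioned survival models (PSMs).

## What it computes

A three-state PSM reads cohort occupancy directly off survival curves —
no transition probabilities:

- progression-free: `PFS(t) = min(S_pfs(t), S_os(t))`
- progressed: `PD(t) = S_os(t) − S_pfs(t)`
- dead: `D(t) = 1 − S_os(t)`

`S_pfs` and `S_os` come from parametric fits (Weibull, exponential,
Gompertz, gamma, log-logistic, log-normal) to right-censored pseudo
individual-patient data, estimated by censored maximum likelihood
`Σ_events ln f(t) + Σ_censored ln S(t)` and selected by AIC (BIC
disagreement is logged). Pseudo-IPD comes either from digitized
Kaplan–Meier coordinates or from a seeded synthetic-trial generator
emulating the CHOICE-01 design (n = 465 at 2:1; median PFS 8.3 vs 5.6
months; PC median OS 17.1 months; 16.2 months median follow-up).

Costs (drugs dosed per body-surface area, administration, monitoring,
hospitalization, second-line mix, hospice, a one-time grade-3/4
adverse-event bundle) and utility-weighted QALYs accrue per 3-week cycle
with half-cycle correction and midpoint discounting (5%/year default)
over a 10-year horizon, yielding the incremental cost-effectiveness
ratio ICER = ΔC/ΔE against a willingness-to-pay threshold of
$37,654/QALY (3× China's 2021 per-capita GDP). One-way (tornado),
probabilistic (1000 Monte Carlo draws; gamma costs, beta utilities,
truncated-normal BSA; CEAC) and scenario analyses (20/30-year horizons,
docetaxel second line) complete the battery.

> **Calibration note.** The unit prices, care costs, utilities and
> adverse-event bundle shipped in the default configuration are clearly
> flagged *placeholders* (see `placeholder_parameters` in
> `src/psmcea/data/default_config.yaml`); the published evaluation's
> supplementary inputs and digitized trial curves are required to
> reproduce its headline ICER. `psmcea run` warns about every
> placeholder it uses.

## Worked example

```bash
psmcea run --mode all --seed 1 --out demo
```

fits all six families to a seeded synthetic trial (log-normal wins by
AIC on these data), runs the PSM and all sensitivity analyses, and
writes CSVs plus a manifest to `demo/run_0001/`. With the packaged
placeholder config, `base_case.csv` contains:

```
arm  cost_usd  qalys  incr_cost_usd  incr_qalys  icer_usd_per_qaly
 PC  14383.14   0.91            NaN         NaN                NaN
 TC  24633.50   1.41       10250.36        0.50           20648.01
```

i.e. TC costs $10,250 more and yields 0.50 more QALYs than PC, an ICER
of $20,648/QALY — cost-effective at the $37,654/QALY threshold (the
absolute level reflects the placeholder prices). `scenarios.csv` shows
the ICER moving to $20,177 (20-year horizon), $20,105 (30-year) and
$12,142 (docetaxel second line, cheaper here than the placeholder
supportive-care cost); `tornado.csv` ranks the toripalimab price,
supportive-care cost and the progressed-state utility as the most
influential inputs; `ceac.csv` gives the probability that TC is
cost-effective at each threshold (1.00 at the WTP under placeholder
variances).

The library surface mirrors the pipeline: `reconstruct_ipd`,
`generate_synthetic_trial`, `fit_distribution`/`select_best`,
`occupancy_trace`, `accumulate_costs`/`accumulate_qalys`, `icer`,
`one_way`, `run_psa`, `run_scenarios` — see `docs/methods.md` for the
modelling details.

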