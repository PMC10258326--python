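# Methods

## Model structure

The model is a three-state partitioned survival model (PSM) for
first-line treatment of advanced NSCLC: progression-free (PFS),
progressed disease (PD), dead. Occupancy at each cycle boundary is read
directly off the two survival functions,

```
pfs(t) = min(S_pfs(t), S_os(t))
pd(t)  = S_os(t) − pfs(t)
dead(t) = 1 − S_os(t)
```

so no transition probabilities are estimated and no memorylessness is
assumed. Because PFS and OS are fitted independently, the extrapolated
PFS curve can cross above OS in the tail; the `min` clamp restores the
structural constraint PFS ≤ OS and keeps PD ≥ 0 while preserving
conservation (the three occupancies sum to 1 to 1e−12 at every cycle —
this is asserted, not assumed).

Cycle length is 21 days, matching the 3-weekly dosing schedule; the
cycle grid ends exactly at the horizon (the final cycle is truncated),
and survival mass beyond the horizon is ignored — no terminal value.
Defaults: 10-year horizon, 5%/year discount on costs and effects
(sensitivity range 0–8%), half-cycle correction on.

## Pseudo individual-patient data

**Reconstruction.** Digitized Kaplan–Meier coordinates `(t_i, S_i)` are
converted to per-subject records by allocating
`k_i = round(n_i · (1 − S_i / Ŝ_{i−1}))` events to interval
`(t_{i−1}, t_i]` against the running risk set `n_i` and the
*reconstructed* survival `Ŝ` (self-correcting, so rounding errors do not
accumulate), with event times at interval midpoints and all remaining
subjects censored administratively at the data cutoff. No interior
censoring is imputed because numbers-at-risk tables are not available
for these curves; the recomputed KM estimator therefore matches each
digitized point within the rounding resolution 0.5/n. Risk-set
calibrated methods that anchor on printed at-risk tables are
deliberately out of scope.

**Synthetic trial.** When no curves are supplied, a seeded generator
emulates the trial design: 465 subjects randomized 2:1, log-normal PFS
and OS with medians 8.3/5.6 months (PFS, TC/PC) and 28/17.1 months (OS).
The TC OS median was *not reached* in the trial (95% CI lower bound 21.7
months); 28 months is a flagged placeholder. Log-scale SD defaults to
0.9 for both endpoints, chosen once to give the long right tail typical
of immunotherapy survival; it is config-overridable.

PFS/OS coupling uses a Gaussian copula: one standard-normal draw drives
OS, a correlated draw (ρ = 0.7 default) drives PFS, so *both marginals
are exactly log-normal at their target medians*, followed by a
`PFS = min(PFS, OS)` clamp. At default parameters the clamp binds for
under ~5% of subjects, so the PFS median calibration is preserved while
the PSM's structural constraint holds for every subject. A
beta-fraction product coupling (PFS = OS × B) was considered and
rejected because it destroys the log-normality and median calibration of
the PFS marginal.

Censoring mimics staggered accrual: entry uniform over a window of half
the target median follow-up, one data cutoff at
`followup_median + window/2`, giving potential follow-up Uniform(0.75m,
1.25m) with median exactly `m` = 16.2 months — closed-form, no tuning.
Both endpoints share a subject's censoring time.

## Survival fitting and selection

Six families (exponential, Weibull, Gompertz, gamma, log-logistic,
log-normal) are fitted by right-censored maximum likelihood. The
parameterizations are fixed and documented in `psmcea.survival`; the
Gompertz shape may be negative (defective, plateau `exp(rate/shape)`),
in which case the fitted median can be infinite. The exponential MLE is
closed-form (events/exposure); other families are optimized on an
unconstrained (log) scale with several data-driven starts, Nelder–Mead
followed by an L-BFGS-B polish (Gompertz and gamma likelihoods are flat
under heavy censoring, hence the multi-start). Non-convergence raises an
error carrying the optimizer messages.

Selection minimizes AIC (`2k − 2ℓ`); BIC (`k ln n − 2ℓ`) is computed and
a disagreement is logged but AIC is authoritative, giving a single
deterministic selection path. Ties break on fewer parameters, then on a
fixed family order. On synthetic log-normal data at trial scale the
procedure recovers the generating family in ≥90% of replicates (tested),
mirroring the published finding that the log-normal fitted both
endpoints best.

## Costs and QALYs

All computation is in USD (1 USD = 6.4515 CNY, the 2021 average, for
any CNY-quoted inputs). Per cycle, discounted at the cycle midpoint:

- **First line** (weighted by PFS occupancy): toripalimab 240 mg flat
  (TC only) every cycle until progression; chemotherapy backbone during
  induction (default 6 cycles, config 4–6) weighted by histology —
  squamous 47.3%: paclitaxel 100 mg/m² ×3 + carboplatin 400 mg/m²;
  non-squamous 52.7%: pemetrexed 500 mg/m² + cisplatin 75 mg/m² or
  carboplatin (50/50 default split); maintenance thereafter: toripalimab
  (TC) plus pemetrexed for the non-squamous fraction (both arms). Doses
  are mg-exact at BSA 1.67 m² (range 1.40–1.94); no vial wastage.
  Administration and PFS-state hospitalization/nursing accrue per cycle;
  surveillance laboratory tests at baseline, every 6 weeks to month 12,
  every 9 weeks after, charged to the cycle they open.
- **Second line** (weighted by PD occupancy): toripalimab for 13.3%
  (TC) / 65.4% (PC) of progressed patients, best supportive care for the
  rest, each per cycle for the whole PD occupancy (no duration cap); a
  scenario switches BSC to docetaxel 75 mg/m² at $0.22/mg. PD-state
  hospitalization accrues per cycle (separately configurable from PFS).
- **One-time**: hospice cost on each cycle's new deaths; the grade-3/4
  (≥5% incidence) adverse-event bundle — Σ incidence × unit cost — in
  cycle 1, with the matching disutility bundle subtracted from QALYs.

QALYs weight half-cycle-corrected person-time by `u_pfs` and `u_pd`
(death = 0). The half-cycle correction applies to both costs and
effects, switchable. The final (partial) cycle pro-rates per-cycle
recurring costs by its width.

ICER = ΔC/ΔE (TC vs PC), undefined when |ΔE| < 1e−9; dominance is
flagged from the signs. The WTP decision is net-monetary-benefit based
(`wtp·ΔE − ΔC ≥ 0`, dominance short-circuiting), which coincides with
the ICER-vs-threshold rule whenever ΔE > 0.

## Sensitivity analyses

- **One-way**: ±20% on cost parameters, ±10% on non-cost parameters,
  the reported 1.40–1.94 m² limits for BSA, 0–8% for the (jointly
  varied) discount rate, and ±36% for the toripalimab price — the
  published description of that band ("36% (20% up or down)") is
  internally inconsistent; we implement ±36%, config-overridable.
  Rows are sorted by ICER span, deterministically (ties by name).
- **PSA**: 1000 iterations; gamma for costs, beta for utilities,
  truncated normal for BSA, each moment-matched to mean = base and
  sd = (high − low)/(2·1.96) from the one-way range (the SD rule is a
  package convention, stated here because the source does not give one).
  Second-line allocation fractions and the discount rate are held fixed
  (no distribution is stated for them). Survival-parameter uncertainty
  is not propagated (the published PSA varies economic inputs). Failed
  iterations are excluded with a recorded count. CEAC over a WTP grid of
  0 to 2× threshold in 200 steps.
- **Scenarios**: 20- and 30-year horizons; docetaxel replacing BSC in
  second line; arbitrary custom deltas. An empty delta reproduces the
  base case bit-exactly.

## Numerical choices

- Discounting at cycle midpoints pairs with the trapezoidal half-cycle
  correction; a constant flow over 10 years at 5% then matches the
  continuous annuity factor `(1 − 1.05⁻¹⁰)/ln 1.05 ≈ 7.913` to 0.1%,
  and discounted life-years match direct numerical integration of
  `S_os(t)(1+r)^{−t}` to 0.2% (both tested).
- Optimizer tolerances: `fatol/xatol` 1e−10 (Nelder–Mead), `ftol` 1e−12
  (L-BFGS-B); median root-finding uses closed forms wherever they exist.
- Monitoring visits that fall exactly on a cycle boundary (6 weeks = two
  cycles) are charged to the cycle they open, via an epsilon shift.
- Degenerate inputs are rejected with named-path errors: <2 events,
  non-positive times, non-monotone digitized curves, utilities outside
  [0,1], second-line fractions not summing to 1, horizons shorter than
  one cycle.

## What the synthetic generator does and does not show

The generator reproduces the trial's design scale, medians, allocation
and follow-up, and the structural PFS ≤ OS coupling. It does **not**
emulate non-proportional hazards or delayed separation typical of
immunotherapy, informative censoring, crossover after progression
(substantial in the trial's control arm), or digitization error. Tests
passing on synthetic data therefore validate the *machinery* (fitting,
selection, accrual, incremental arithmetic), not the clinical
extrapolation itself.

## Known limitations

- The headline published results (base-case ICER $32,237/QALY, scenario
  ICERs, the 90% CEAC probability) depend on supplementary unit costs,
  utilities and digitized trial curves that are not in the open-access
  text; with the flagged placeholder inputs the package produces
  internally consistent but *not calibrated* absolute values. Replace
  every `placeholder_parameters` entry and supply the four digitized
  curves to attempt calibration.
- Costing granularity: hospitalization/nursing accrue per cycle in both
  alive states (the source does not say which); second-line toripalimab
  runs for the whole PD occupancy by default (duration uncapped).
- No background general-population mortality, cure fraction, or
  covariate adjustment; subgroups and budget impact are out of scope.
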