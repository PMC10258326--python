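# Default model configuration: toripalimab + chemotherapy (TC) vs
# chemotherapy (PC), first-line advanced NSCLC, Chinese healthcare
# system perspective.
#
# Trial-anchored values (arm sizes, medians, follow-up, dosing, BSA,
# second-line allocation, docetaxel price, WTP, exchange rate) are taken
# from the published CHOICE-01 evidence base.  Values listed under
# `placeholder_parameters` are NOT published in the open-access text
# (they live in supplementary cost/utility tables held by the original
# analysts): they are round-number placeholders in the range of
# comparable Chinese NSCLC evaluations and MUST be replaced with local
# unit costs and utilities before any decision use.
meta:
  description: "TC vs PC partitioned survival cost-effectiveness model"
  currency: USD
  cny_per_usd: 6.4515

trial:
  n_total: 465
  allocation: [2, 1]          # TC : PC
  pfs_median_tc: 8.3          # months
  pfs_median_pc: 5.6
  os_median_tc: 28.0          # placeholder: median OS not reached (95% CI 21.7-NE)
  os_median_pc: 17.1
  log_sd_pfs: 0.9
  log_sd_os: 0.9
  followup_median: 16.2       # months
  copula_rho: 0.7

model:
  cycle_length_days: 21
  horizon_years: 10
  discount_rate_costs: 0.05
  discount_rate_effects: 0.05
  half_cycle_correction: true
  wtp: 37654.0                # 3x China 2021 per-capita GDP, USD/QALY
  selection_criterion: aic

population:
  bsa: 1.67                   # m^2, mean
  bsa_low: 1.40
  bsa_high: 1.94
  squamous_fraction: 0.473
  cisplatin_fraction_nonsquamous: 0.5

treatment:
  induction_cycles: 6         # trial allows 4-6
  toripalimab_mg_per_cycle: 240
  doses_mg_per_m2:            # [dose per administration, administrations/cycle]
    paclitaxel: [100, 3]      # days 1, 8, 15 (squamous)
    carboplatin: [400, 1]
    pemetrexed: [500, 1]      # non-squamous, also maintenance
    cisplatin: [75, 1]
    docetaxel: [75, 1]        # second-line scenario only

prices_usd_per_mg:
  toripalimab: 1.756          # placeholder
  paclitaxel: 0.09            # placeholder
  carboplatin: 0.04           # placeholder
  cisplatin: 0.02             # placeholder
  pemetrexed: 0.35            # placeholder
  docetaxel: 0.22             # published scenario price

costs_usd:
  administration_per_cycle: 50.0        # placeholder
  laboratory_test: 120.0                # placeholder, per surveillance visit
  hospitalization_per_cycle_pfs: 60.0   # placeholder
  hospitalization_per_cycle_pd: 60.0    # placeholder
  bsc_per_cycle: 200.0                  # placeholder
  hospice_one_time: 1800.0              # placeholder

second_line:                  # fractions of progressed patients, per arm
  TC: {toripalimab: 0.133, bsc: 0.867}
  PC: {toripalimab: 0.654, bsc: 0.346}
  bsc_drug: null              # set to "docetaxel" for the scenario analysis

utilities:
  pfs: 0.804                  # placeholder
  pd: 0.321                   # placeholder

adverse_events:               # grade 3/4, incidence >= 5% in either arm
  # placeholders: names/incidences in the range reported for
  # platinum-doublet +/- PD-1 regimens; costs/disutilities are one-time
  - {name: neutropenia,      incidence: {TC: 0.40, PC: 0.38}, cost_usd: 450.0, disutility: 0.012}
  - {name: leukopenia,       incidence: {TC: 0.25, PC: 0.24}, cost_usd: 300.0, disutility: 0.008}
  - {name: anemia,           incidence: {TC: 0.18, PC: 0.16}, cost_usd: 500.0, disutility: 0.010}
  - {name: thrombocytopenia, incidence: {TC: 0.15, PC: 0.14}, cost_usd: 700.0, disutility: 0.011}

placeholder_parameters:
  - trial.os_median_tc
  - prices_usd_per_mg.toripalimab
  - prices_usd_per_mg.paclitaxel
  - prices_usd_per_mg.carboplatin
  - prices_usd_per_mg.cisplatin
  - prices_usd_per_mg.pemetrexed
  - costs_usd.administration_per_cycle
  - costs_usd.laboratory_test
  - costs_usd.hospitalization_per_cycle_pfs
  - costs_usd.hospitalization_per_cycle_pd
  - costs_usd.bsc_per_cycle
  - costs_usd.hospice_one_time
  - utilities.pfs
  - utilities.pd
  - adverse_events

# Optional: digitized Kaplan-Meier curve files (time_months,survival CSV).
# When all four are given the pipeline reconstructs pseudo-IPD from them
# instead of generating a synthetic trial.
digitized_curves:
  TC: {PFS: null, OS: null}
  PC: {PFS: null, OS: null}
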