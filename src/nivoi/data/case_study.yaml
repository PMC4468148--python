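# Case study: individually tailored vs two-year elastic compression stocking
# (ECS) therapy for prevention of post-thrombotic syndrome (PTS) after
# deep-vein thrombosis.
#
# Entries marked appendix_default are documented placeholders for quantities
# (resource use, unit prices, utility norms, mortality, severity split) that
# the published evidence base does not pin down; they are set to values a
# Dutch health-economic analysis would consider realistic and are meant to be
# overridden when better estimates are available.

model:
  threshold: 20000            # EUR per QALY
  discount_cost: 0.04         # annual, Dutch guideline
  discount_effect: 0.015      # annual, Dutch guideline
  start_age: 60               # years at index DVT (placeholder)
  max_age: 100                # lifetime horizon cap
  severity_split_mild: 0.8    # share of PTS onsets that are mild-to-moderate (placeholder)
  stop_fraction_6mo: 0.5      # tailored arm: fraction safely stopping ECS at month 6
  stocking_cost_per_year: 100     # EUR per wearer-year
  homecare_cost_per_year: 10000   # EUR per year, patients needing stocking application
  gompertz_slope: 0.09        # background mortality log-hazard slope (placeholder)
  life_expectancy: 80         # years; calibrates the Gompertz intercept (placeholder)
  utility_norm_base: 0.95     # population norm utility at/below the reference age (placeholder)
  utility_norm_slope: 0.002   # utility decline per year above the reference age (placeholder)
  utility_norm_ref_age: 40

population:
  annual_incidence: 25000     # patients per year affected by the adoption decision
  tech_lifetime: 10           # years
  population_discount_rate: 0.04
  discount_population: true   # discount future incident cohorts

trial:
  fixed_cost: 10000           # EUR
  cost_per_patient: 5000      # EUR per included patient
  allocation_ratio: 1.0       # tailored : standard

voi:
  sample_size_grid: [25, 100, 400, 500, 700, 1000, 1500, 5000]
  outer: 200                  # simulated trials per sample size
  inner: 1000                 # posterior PSA draws per simulated trial
  psa_draws: 10000            # baseline probabilistic sensitivity analysis
  updated_parameters: [q1, q2, q3, rr_tailored]

parameters:
  # cumulative PTS incidence with two-year ECS therapy (standard arm)
  - name: cum_inc_6m
    family: beta-by-moments
    mean: 0.211
    se: 0.0429
    units: proportion
  - name: cum_inc_12m
    family: beta-by-moments
    mean: 0.222
    se: 0.0431
    units: proportion
  - name: cum_inc_24m
    family: beta-by-moments
    mean: 0.245
    se: 0.0454
    units: proportion
  # relative risk of PTS onset after month 6 with tailored therapy;
  # lognormal on the RR, censored below at 1 (tailored is at best equal)
  - name: rr_tailored
    family: lognormal-censored
    sigma_log: 0.612
    censor_at: 1.0
    units: relative risk
  # quality-of-life consequences
  - name: disutility_mild_pts
    family: beta-by-moments
    mean: 0.117
    se: 0.050
    units: utility decrement
  - name: disutility_severe_pts
    family: beta-by-moments
    mean: 0.218
    se: 0.040
    units: utility decrement
  - name: disutility_ecs
    family: beta-by-moments
    mean: 0.02
    se: 0.01
    units: utility decrement while wearing stockings
    appendix_default: true
  # annual treatment costs of prevalent PTS
  - name: cost_mild_pts
    family: gamma-by-moments
    mean: 2000
    se: 500
    units: EUR per year
    appendix_default: true
  - name: cost_severe_pts
    family: gamma-by-moments
    mean: 7000
    se: 1750
    units: EUR per year
    appendix_default: true
  # fraction of wearers needing home care to apply/remove stockings
  - name: homecare_fraction
    family: beta-by-moments
    mean: 0.075
    se: 0.02
    units: proportion
    appendix_default: true
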