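# nivoi — value-of-information sample sizing for non-inferiority trials

`nivoi` compares two ways of choosing the sample size of a two-arm
non-inferiority trial:

* the **classic frequentist calculation** (Blackwelder): the smallest n that
  proves, at one-sided level α with power 1−β, that the new therapy loses at
  most a prespecified margin δ of the standard therapy's effect; and
* a **decision-theoretic calculation**: a probabilistic cost-effectiveness
  model propagates parameter uncertainty into net monetary benefit
  NMB = λ·QALY − cost, and the value of a trial of size n is what the
  expected trial data would be worth to the adoption decision
  (expected value of sample information, EVSI) net of trial costs
  (expected net benefit of sampling, ENBS).  The optimal n maximises ENBS.

The package is aimed at health economists and trial statisticians.  It ships
a worked case study: individually tailored duration of elastic compression
stocking (ECS) therapy versus the standard two years of ECS for preventing
post-thrombotic syndrome (PTS) after deep-vein thrombosis (DVT).  Tailored
therapy is expected to be at best equally effective but cheaper and less
burdensome — exactly the setting where a non-inferiority design is used and
where the frequentist calculation ignores the quantities (costs, quality of
life, home-care burden) that motivate the trial in the first place.

## The models

**Frequentist.**  With success proportions p_S, p_E, margin δ > p_S − p_E:

    n/group = (z_{1−α} + z_{1−β})² · (p_S(1−p_S) + p_E(1−p_E)) / (p_S − p_E − δ)²

and the one-sided test concludes non-inferiority when
z = (p̂_E − p̂_S + δ)/SE > z_{1−α}.

**Decision-theoretic.**  A four-state cohort model
(No PTS → {mild-to-moderate PTS, severe PTS} → death; six-month cycles for
the first year, annual thereafter, lifetime horizon) yields discounted costs
C(j,θ) and QALYs H(j,θ) per strategy j under parameter vector θ.  Priors:
Beta (moment-matched) for the cumulative PTS incidences at 6/12/24 months
and for proportions/disutilities, Gamma for costs, and a lognormal relative
risk (RR) censored below at 1 multiplying the post-6-month onset
probabilities of the tailored strategy.  From a probabilistic sensitivity
analysis the package computes, per patient and for the discounted effective
population p:

    EVPI      = E_θ[max_j NMB] − max_j E_θ[NMB]
    EVPPI(φ)  = E_φ[max_j E_ψ NMB] − max_j E[NMB]          (nested MC)
    EVSI(n)   = E_X[max_j E_{θ|X} NMB] − max_j E_θ[NMB]    (simulated trials X
                of size n, conjugate Beta-binomial and normal log-RR updates)
    ENBS(n)   = (p − n)·EVSI(n) − (fixed cost + per-patient cost · n)

## Worked example

Frequentist sample size for the case design (PTS-free proportion 0.233 in
both arms, margin 7.5 points, one-sided 5%, power 80%):

```text
$ nivoi freq-n --pS 0.233 --pE 0.233 --delta 0.075 --alpha 0.05 --power 0.8
z_alpha = 1.6449, z_beta = 0.8416
variance sum = 0.357422, squared margin distance = 0.005625
exact n per group = 392.85 (ceil-per-group)
n per group = 393
n total = 786
```

786 patients in total (exact normal quantiles, ceiling per group; published
analyses using rounded constants print up to 788 — the intermediates make
the convention auditable).

Expected value of perfect information under the shipped case configuration:

```text
$ nivoi --seed 1 evpi -k 10000
EVPI per patient: 559.31 EUR (SE 4.40)
effective population: 202772
population EVPI: 113411655 EUR
```

Decision uncertainty costs ~€559 per patient; over the 202,772 patients
affected by the decision (25,000/year for 10 years, discounted at 4%) about
€113 million is at stake, so a trial is clearly worth considering.  The full
comparison — PSA summary, EVPI, EVPPI, the EVSI/ENBS curve over
n ∈ {25, …, 5000} and a report juxtaposing both sample sizes — is written by

```sh
nivoi --seed 1 --outdir out case-study --mode full     # ~1 min
```

Note that costs, utility norms, mortality and the PTS severity split are
documented placeholders (flagged `appendix_default` in
`src/nivoi/data/case_study.yaml`); EVSI/ENBS levels and the resulting
optimal n depend on them.  Override the config to use your own estimates.

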