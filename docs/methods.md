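# Methods

This note documents the models implemented in `nivoi`, the assumptions and
defaults behind them, and the numerical choices that matter when
interpreting output.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Decision problem

Two strategies for preventing post-thrombotic syndrome (PTS) after
deep-vein thrombosis are compared: standard therapy (elastic compression
stockings, ECS, worn for 24 months) and individually tailored therapy (all
patients wear ECS for 6 months; a fraction judged safe then stops, the rest
continue to 24 months).  Tailored therapy is assumed at best equally
effective — its PTS risk after month 6 is the standard risk multiplied by a
relative risk RR ≥ 1 — but it reduces stocking and home-care costs and the
wearing burden.  The adoption decision is made on expected net monetary
benefit, NMB = λ·QALY − cost, with willingness to pay λ = €20,000/QALY.

## 2. Cohort model

Four states: `NoPTS`, `MildModPTS`, `SeverePTS`, `Death`.  The cycle plan is
two 6-month cycles followed by annual cycles; the horizon is "lifetime",
implemented as a cap at age 100 from a starting age of 60 (40 model years).

* **Onset.**  PTS onset occurs only in the first three cycles, i.e. the two
  years covered by the incidence evidence; no later onset is modelled.
  Cumulative incidences c6 ≤ c12 ≤ c24 are converted to conditional
  per-interval probabilities q1 = c6, q2 = (c12−c6)/(1−c6),
  q3 = (c24−c12)/(1−c12); the recomposition is exact.  Under tailored
  therapy q2 and q3 are multiplied by RR (clamped at 1); q1 is not — the
  arms are identical until the tailoring decision at month 6.
* **Severity.**  Onset splits into mild-to-moderate vs severe PTS by a fixed
  proportion (default 0.8/0.2).  PTS states are chronic: no reversion and no
  progression between severities.  The published evidence names the states
  but not transitions among them; the simplest consistent structure is used.
* **Mortality.**  Age-dependent background mortality with a Gompertz hazard
  h(a) = A·e^{0.09a}, the intercept A calibrated so life expectancy at birth
  is 80 years (solved by root finding on the survival integral).  PTS
  confers no excess mortality.  Within a cycle, mortality applies first and
  onset among survivors second.  Setting `life_expectancy` to infinity
  switches mortality off, which the analytic tests exploit.
* **Payoffs.**  Costs: an ECS cost per wearer-year (stockings €100 plus a
  home-care fraction, prior mean 7.5%, at €10,000/year) during the
  strategy's wearing schedule, and annual PTS treatment costs by severity.
  Utilities: an age-declining population norm minus state disutilities
  (mild-to-moderate 0.117, severe 0.218) and a small ECS wearing disutility.
  Negative state utilities are clamped at 0 with a runtime warning.
* **Discounting.**  4%/year for costs, 1.5%/year for effects (Dutch
  guidelines), annual compounding evaluated at each cycle's start; no
  half-cycle correction.  The choice is isolated in one function; with
  6-month early cycles and small rates the half-cycle effect is well below
  the Monte Carlo noise of any value-of-information quantity.

The engine is vectorised over parameter draws; the single-draw API
(`run_cohort`, `discounted_ce`) and the batch API (`evaluate_strategies`)
share the same transition and payoff construction and agree to machine
precision (tested).

## 3. Priors

| parameter | family | mean (SE) | source status |
|---|---|---|---|
| cumulative PTS incidence 6/12/24 m | Beta by moments | 0.211 (0.0429), 0.222 (0.0431), 0.245 (0.0454) | trial evidence |
| RR of onset after month 6 (tailored) | lognormal on RR, censored at 1 | σ_log = 0.612 (97.5% quantile ≈ 3.32) | margin-matched |
| disutility mild-mod / severe PTS | Beta by moments | 0.117 (0.050) / 0.218 (0.040) | literature norms |
| ECS wearing disutility | Beta by moments | 0.02 (0.01) | placeholder |
| annual cost mild / severe PTS | Gamma by moments | €2,000 (500) / €7,000 (1,750) | placeholder (severe scale from US claims data) |
| home-care fraction | Beta by moments | 0.075 (0.02) | placeholder |

Moment matching is exact: Beta(α,β) with v = m(1−m)/s² − 1, α = mv,
β = (1−m)v; Gamma(shape = m²/s², rate = m/s²).  Infeasible moments
(s² ≥ m(1−m)) raise an error rather than being silently truncated.

**Joint incidence sampling.**  The three cumulative incidences come from one
follow-up cohort, but their dependence is not published.  Sampling them
independently would produce non-monotone triplets.  Instead the conditional
probabilities q1, q2, q3 are given independent Beta priors refit by moment
matching — q1 keeps the reported (mean, SE); q2 and q3 get binomial SEs on
at-risk sets N(1−c6) and N(1−c12), where N = c6(1−c6)/SE6² ≈ 90 is the
effective cohort size implied by the 6-month estimate — and the cumulative
values are recomposed.  Monotonicity then holds in every draw by
construction, and the implied information content matches a single cohort
of ~90 patients rather than three independent ones.

**Censored RR.**  Draws are max(e^Z, 1), Z ~ N(0, 0.612²).  The censored
median is exactly 1; the 97.5% quantile, ≈3.32, corresponds to lifting the
24-month incidence from 24.5% to ≈32%, i.e. the 7.5-point non-inferiority
margin (tested).  Closed forms for the censored mean and quantiles serve as
oracles for the sampler.

**Randomness.**  One master seed; every stage (PSA, EVSI outer, EVSI inner,
baseline, …) draws from an independent named substream
(`SeedSequence(seed, spawn_key=crc32(name))`), so changing one loop's size
never perturbs another and all outputs are bit-reproducible given the seed.

## 4. PSA and value of information

The PSA evaluates both strategies on the *same* draws (common random
parameters), which is required for coherent incremental and VOI analysis.
Per-draw argmax ties in `P(best)` summaries are split half-and-half; under
continuous priors they have probability zero.

* **EVPI** per patient: mean over draws of (max_j NMB − NMB_{j*}), with j*
  the strategy with highest mean NMB.  Exactly zero under zero-variance
  priors.
* **Effective population**: Σ_{t=1..L} incidence/(1+r)^t, discounted at the
  cost rate (4%) over the technology lifetime (10 years).  An undiscounted
  option exists (`discount_population: false`).  With 25,000 patients/year
  this gives ≈202,772.
* **EVPPI(φ)**: nested Monte Carlo; outer draws of φ, inner draws of the
  (a priori independent) complement.
* **EVSI(n)**: outer loop — draw θ_true from the priors, simulate a 1:1
  two-arm trial of total size n (per-arm multinomial over onset in 0–6,
  6–12, 12–24 months vs PTS-free), update the priors in closed form; inner
  loop — posterior PSA.  Updated parameters: q1–q3 by conjugate
  Beta-binomial from the standard arm (those parameters describe standard
  therapy; the tailored arm informs them only through RR), and log RR by a
  precision-weighted normal update.  The RR data summary is the ratio of
  conditional post-6-month onset proportions among patients PTS-free at
  month 6 — the quantity RR actually multiplies.  Summarising by the
  24-month *cumulative* ratio instead would be diluted by the shared
  0–6-month incidence, under-identify RR, and make the "EVSI" computed from
  the mis-calibrated posterior exceed EVPI; the conditional contrast keeps
  the update coherent with the generating process (parameter recovery at
  RR = 2 is tested).  Trials with a zero cell in either arm's post-6-month
  window keep the RR prior, are flagged, and are counted in the
  `zero_cell_fraction` diagnostic — no silent continuity corrections.
* **Estimator form.**  All nested estimators report the mean per-outer
  replicate *gain* max_j m_j − m_{j*} (m_j = inner-mean NMB; j* = the
  current-information best strategy).  For EVPPI this is algebraically the
  textbook E_φ[max_j E_ψ NMB] − max_j E NMB on the same draws; for EVSI it
  is unbiased for E_X[max_j E_{θ|X} NMB] − max_j E_θ NMB because the prior
  expectation of the posterior-mean NMB equals the prior mean.  Differencing
  inside the replicate cancels the (large) common level variation, so the
  reported outer-loop standard errors are of the VOI quantity itself.  Gains
  are nonnegative by construction; a residual upward bias of order the
  inner-loop noise at the decision boundary remains, as in any nested MC
  estimator.  A trial of size 0 is short-circuited to EVSI = 0 exactly.
* **Population EVSI and ENBS.**  Population EVSI multiplies by the effective
  population minus the n trial participants (removed from the first-year
  cohort before discounting; the difference between conventions is
  negligible and documented).  ENBS(n) = population EVSI − (€10,000 +
  €5,000·n).  The optimal n is the grid argmax (default grid
  {25, 100, 400, 500, 700, 1000, 1500, 5000}); no smoothing or
  interpolation, ties go to the smallest n.

Default Monte Carlo sizes: 10,000 PSA draws; 200 outer × 1000 inner for
EVPPI/EVSI.  The case-study driver's scaled-down mode (50 × 200, 4-point
grid) and the smaller loops used in parts of the test suite were chosen so
each analysis completes in seconds while leaving the 3-standard-error
acceptance tolerances meaningful.

## 5. What the trial simulator does and does not emulate

The synthetic trials reproduce the design being costed: two parallel arms,
1:1 allocation (rounding preserves the total), multinomial interval onset
counts under the cohort model's own probabilities, and truths drawn from
the priors.  They do **not** model dropout, non-adherence, interim analyses,
measurement error in PTS assessment, or recruitment over calendar time.
Passing tests therefore demonstrate internal coherence of the
prior → trial → posterior → value chain, not robustness of EVSI to the
messiness of real trials — a real application should treat the simulator's
idealisations as a lower bound on residual uncertainty.

## 6. Numerical choices

* Cohort conservation is enforced to 1e-12 row-sum tolerance in tests.
* Frequentist n: exact normal quantiles, ceiling per group, doubled.  With
  the case inputs this gives 786; published analyses using rounded z values
  print up to 788.  All intermediates are exposed.
* The non-inferiority margin check uses a 1e-9 relative tolerance so a
  deficit exactly at the margin is rejected despite float rounding.
* Beta/Gamma moment fits are validated against analytic moments to 1e-10
  relative error (property-tested).
* Strict config parsing: unknown or missing keys fail loudly, naming the key.

## 7. Known limitations

* Resource use, unit prices, utility norms, the mortality table, the
  severity split and the starting age are placeholders (flagged
  `appendix_default`), so absolute € results — EVPI/EVSI levels and hence
  the ENBS-optimal n — are configuration-dependent.  Under the shipped
  placeholders the EVSI curve is still rising at n = 5000 and the grid
  argmax lands at the top of the grid; with different (e.g. steeper-cost or
  lower-value) configurations it moves to interior grid points.  The
  orderings, identities and calibration properties in the test suite hold
  regardless.
* No PTS severity progression, no excess PTS mortality, no treatment
  switching beyond the single month-6 decision.
* EVPPI/EVSI use nested Monte Carlo only; no regression metamodels.
* The RR update is approximate (delta-method normal likelihood on the log
  ratio); it contracts correctly and recovers large-trial truths, but very
  small trials mostly return the prior (high `zero_cell_fraction`).
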