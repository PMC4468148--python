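"""Value-of-information analysis: EVPI, EVPPI, EVSI and ENBS.

All estimators are Monte Carlo:

* EVPI per patient:  E_theta[max_j NMB] - max_j E_theta[NMB], from a PSA.
* EVPPI(phi): nested Monte Carlo — outer draws of the parameter subset phi,
  inner draws of the complement, E_phi[max_j E_psi NMB] - max_j E[NMB].
* EVSI(n): outer loop simulates trials of total size n under prior-drawn
  truths and updates the priors (closed form, see :mod:`nivoi.trial`); the
  inner loop is a posterior PSA; per-patient EVSI is
  E_X[max_j E_{theta|X} NMB] - max_j E_theta[NMB].
* ENBS(n) = population EVSI(n) - trial cost (fixed + per-patient * n); the
  optimal sample size is the grid argmax (ties -> smallest n).

Population quantities multiply per-patient values by the *effective
population*: the discounted number of patients affected by the adoption
decision over the technology's lifetime.  For EVSI the trial participants
are subtracted from the first-year incident cohort, since they do not
benefit from the information the trial produces.

Every estimate carries a standard error from the outer-loop replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markov
from ._streams import stream
from .params import (
    CUMULATIVE_INCIDENCE_NAMES,
    RR_NAME,
    ModelConfig,
    ParamSpec,
    conditional_incidence_specs,
    incidence_prior_betas,
)
from .psa import PSAResult, run_psa
from .trial import TrialDesign, posterior_from_trial, simulate_trial

__all__ = [
    "VOIEstimate",
    "VOIResult",
    "evpi_from_nmb",
    "evpi_per_patient",
    "effective_population",
    "population_evpi",
    "evppi",
    "evsi",
    "enbs",
    "run_voi",
]


@dataclass(frozen=True)
class VOIEstimate:
    """A Monte Carlo value-of-information estimate with its standard error."""

    value: float
    se: float


# ---------------------------------------------------------------------------
# EVPI


def evpi_from_nmb(nmb: np.ndarray) -> VOIEstimate:
    """Per-patient EVPI from a (K, n_strategies) NMB matrix."""
    nmb = np.asarray(nmb, dtype=float)
    if nmb.ndim != 2 or nmb.shape[0] < 2:
        raise ValueError("need a (K >= 2, n_strategies) NMB matrix")
    j_star = int(np.argmax(nmb.mean(axis=0)))
    gain = nmb.max(axis=1) - nmb[:, j_star]
    return VOIEstimate(value=float(gain.mean()),
                       se=float(gain.std(ddof=1) / math.sqrt(len(gain))))


def evpi_per_patient(psa: PSAResult) -> VOIEstimate:
    """Per-patient EVPI (EUR) from a probabilistic sensitivity analysis."""
    if psa.k < 100:
        raise ValueError("need K >= 100 PSA draws for a stable EVPI")
    return evpi_from_nmb(psa.nmb)


# ---------------------------------------------------------------------------
# effective population


def effective_population(annual_incidence: float, tech_lifetime_years: float,
                         discount_rate: float) -> float:
    """Discounted count of patients affected over the technology lifetime.

    Sum over years t = 1..L of incidence/(1+r)^t, i.e. incidence times the
    annuity factor (1-(1+r)^-L)/r; the r = 0 limit is incidence * L.
    """
    if annual_incidence <= 0 or tech_lifetime_years <= 0:
        raise ValueError("annual incidence and technology lifetime must be > 0")
    if discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    if discount_rate == 0.0:
        return annual_incidence * tech_lifetime_years
    r = discount_rate
    annuity = (1.0 - (1.0 + r) ** (-tech_lifetime_years)) / r
    return annual_incidence * annuity


def _config_population(config: ModelConfig, n_trial: int = 0) -> float:
    """Effective population, optionally net of trial participants.

    Trial patients are removed from the first incident cohort before
    discounting (they are recruited immediately).
    """
    r = config.population_discount_rate if config.discount_population else 0.0
    p = effective_population(config.annual_incidence, config.tech_lifetime, r)
    if n_trial:
        p -= n_trial / (1.0 + r)
    return max(p, 0.0)


def population_evpi(evpi_pp: float, eff_population: float) -> float:
    """Population EVPI: per-patient EVPI times the effective population."""
    if evpi_pp < 0 or eff_population < 0:
        raise ValueError("inputs must be >= 0")
    return evpi_pp * eff_population


# ---------------------------------------------------------------------------
# shared sampling helpers


def _sampling_specs(specs: list[ParamSpec]) -> dict[str, ParamSpec]:
    """Independent sampling parameters: conditional incidences replace the
    cumulative triplet; everything else passes through."""
    out = {s.name: s for s in conditional_incidence_specs(specs)}
    for s in specs:
        if s.name not in CUMULATIVE_INCIDENCE_NAMES:
            out[s.name] = s
    return out


def _inner_means(nmb_flat: np.ndarray, outer: int, inner: int) -> np.ndarray:
    """(outer, n_strategies) matrix of inner-loop mean NMB per strategy."""
    return nmb_flat.reshape(outer, inner, -1).mean(axis=1)


def _gain_estimate(inner_means: np.ndarray, j_star: int) -> VOIEstimate:
    """Estimate E_outer[max_j m_j] - E[m_{j*}] as the mean per-replicate gain.

    Differencing against the current best strategy j* inside each outer
    replicate cancels the common level variation, so the reported standard
    error reflects the uncertainty of the value-of-information estimate
    itself rather than of the absolute NMB level.  The per-replicate gain is
    nonnegative by construction.
    """
    gain = inner_means.max(axis=1) - inner_means[:, j_star]
    return VOIEstimate(value=float(gain.mean()),
                       se=float(gain.std(ddof=1) / math.sqrt(len(gain))))


# ---------------------------------------------------------------------------
# EVPPI


def evppi(config: ModelConfig, specs: list[ParamSpec], subset: list[str],
          outer: int, inner: int, seed: int) -> VOIEstimate:
    """Per-patient EVPPI of the parameter subset ``subset`` (nested MC).

    Subset names refer to sampling parameters (q1, q2, q3, rr_tailored,
    disutility_*, cost_*, ...); parameters are a priori independent, so the
    inner draws of the complement are unconditional.
    """
    samp = _sampling_specs(specs)
    unknown = set(subset) - set(samp)
    if unknown:
        raise ValueError(f"unknown parameter names {sorted(unknown)}")
    if not subset:
        raise ValueError("subset must be nonempty")
    if outer < 2 or inner < 2:
        raise ValueError("outer and inner must be >= 2")
    rng = stream(seed, "evppi")
    k = outer * inner
    theta: dict[str, np.ndarray] = {}
    for name, spec in samp.items():
        if name in subset:
            theta[name] = np.repeat(spec.sample(outer, rng), inner)
        else:
            theta[name] = spec.sample(k, rng)
    costs, qalys = markov.evaluate_strategies(config, theta)
    nmb = config.threshold * qalys - costs
    j_star = int(np.argmax(nmb.mean(axis=0)))
    return _gain_estimate(_inner_means(nmb, outer, inner), j_star)


# ---------------------------------------------------------------------------
# EVSI


def evsi(config: ModelConfig, specs: list[ParamSpec],
         grid: list[int] | None = None, outer: int | None = None,
         inner: int | None = None, seed: int = 0) -> pd.DataFrame:
    """EVSI curve over a grid of total trial sizes.

    Returns one row per n with per-patient EVSI, the (trial-corrected)
    effective population, population EVSI, the outer-loop MC standard error
    (per patient and population scale) and the fraction of simulated trials
    whose RR update was skipped because of a zero cell.
    """
    grid = list(config.sample_size_grid if grid is None else grid)
    outer = config.outer if outer is None else outer
    inner = config.inner if inner is None else inner
    if not grid:
        raise ValueError("sample-size grid must be nonempty")
    if outer < 2 or inner < 2:
        raise ValueError("outer and inner must be >= 2")

    samp = _sampling_specs(specs)
    prior_betas = incidence_prior_betas(specs)
    rr_spec = next(s for s in specs if s.name == RR_NAME)
    prior_mu, prior_sigma, censor = 0.0, rr_spec.sigma_log, rr_spec.censor_at
    other_names = [n for n in samp
                   if n not in ("q1", "q2", "q3", RR_NAME)]

    # current-information decision: the strategy with highest prior mean NMB.
    # Per-replicate differencing against it makes the EVSI estimator a mean
    # of nonnegative gains (E[posterior mean NMB] equals the prior mean by
    # the law of total expectation, so the difference is unbiased).
    rng_base = stream(seed, "evsi-baseline")
    base_psa = run_psa(config, specs, k=max(outer * inner, 1000), rng=rng_base)
    baseline = float(base_psa.nmb.mean(axis=0).max())
    j_star = int(np.argmax(base_psa.nmb.mean(axis=0)))

    rng_outer = stream(seed, "evsi-outer")
    rng_inner = stream(seed, "evsi-inner")
    rows = []
    for n in grid:
        if n == 0:
            # a trial of size zero carries no information: posterior = prior
            pop = _config_population(config)
            rows.append({"n": 0, "evsi_per_patient": 0.0, "evsi_se_per_patient": 0.0,
                         "effective_population": pop, "population_evsi": 0.0,
                         "population_evsi_se": 0.0, "zero_cell_fraction": 1.0})
            continue
        design = TrialDesign(n_total=int(n), allocation_ratio=config.allocation_ratio,
                             fixed_cost=config.trial_fixed_cost,
                             cost_per_patient=config.trial_cost_per_patient)
        post_a = np.empty((outer, 3))
        post_b = np.empty((outer, 3))
        post_mu = np.empty(outer)
        post_sigma = np.empty(outer)
        skipped = 0
        truths = {name: spec.sample(outer, rng_outer) for name, spec in samp.items()}
        for o in range(outer):
            theta_true = {k: truths[k][o] for k in ("q1", "q2", "q3", RR_NAME)}
            outcome = simulate_trial(design, theta_true, rng_outer)
            post = posterior_from_trial(prior_betas, prior_mu, prior_sigma, outcome)
            post_a[o] = [ab[0] for ab in post.q_betas]
            post_b[o] = [ab[1] for ab in post.q_betas]
            post_mu[o] = post.logrr_mu
            post_sigma[o] = post.logrr_sigma
            skipped += 0 if post.rr_updated else 1

        # posterior PSA: updated parameters from their posteriors, the rest
        # from their priors (a priori independence)
        theta: dict[str, np.ndarray] = {}
        for i, qname in enumerate(("q1", "q2", "q3")):
            theta[qname] = rng_inner.beta(post_a[:, i, None], post_b[:, i, None],
                                          size=(outer, inner)).ravel()
        z = rng_inner.normal(post_mu[:, None], post_sigma[:, None], size=(outer, inner))
        theta[RR_NAME] = np.maximum(np.exp(z), censor).ravel()
        for name in other_names:
            theta[name] = samp[name].sample(outer * inner, rng_inner)

        costs, qalys = markov.evaluate_strategies(config, theta)
        nmb = config.threshold * qalys - costs
        est = _gain_estimate(_inner_means(nmb, outer, inner), j_star)
        pop = _config_population(config, n_trial=int(n))
        rows.append({
            "n": int(n),
            "evsi_per_patient": est.value,
            "evsi_se_per_patient": est.se,
            "effective_population": pop,
            "population_evsi": est.value * pop,
            "population_evsi_se": est.se * pop,
            "zero_cell_fraction": skipped / outer,
        })
    df = pd.DataFrame(rows)
    df.attrs.update({"outer": outer, "inner": inner, "seed": seed,
                     "baseline_nmb": baseline})
    return df


def enbs(evsi_curve: pd.DataFrame, fixed_cost: float, cost_per_patient: float
         ) -> tuple[pd.DataFrame, int]:
    """Expected net benefit of sampling and the optimal sample size.

    ENBS(n) = population EVSI(n) - (fixed + per-patient * n); the optimal n
    is the grid argmax, ties resolved to the smallest n.
    """
    if len(evsi_curve) == 0:
        raise ValueError("EVSI curve is empty")
    out = evsi_curve.copy()
    out["trial_cost"] = fixed_cost + cost_per_patient * out["n"]
    out["enbs"] = out["population_evsi"] - out["trial_cost"]
    out["enbs_se"] = out.get("population_evsi_se", 0.0)
    best = int(out.loc[out["enbs"].idxmax(), "n"])
    return out, best


# ---------------------------------------------------------------------------
# end-to-end convenience


@dataclass(frozen=True)
class VOIResult:
    """Bundle of all value-of-information outputs for one configuration."""

    evpi_per_patient: VOIEstimate
    effective_population: float
    population_evpi: float
    evppi_per_patient: dict[str, VOIEstimate]
    evsi_curve: pd.DataFrame  # includes ENBS columns
    optimal_n: int
    settings: dict = field(default_factory=dict)


def run_voi(config: ModelConfig, specs: list[ParamSpec], seed: int,
            outer: int | None = None, inner: int | None = None,
            grid: list[int] | None = None,
            evppi_subsets: dict[str, list[str]] | None = None) -> VOIResult:
    """Run the full VOI pipeline: PSA -> EVPI -> EVPPI -> EVSI -> ENBS."""
    psa_res = run_psa(config, specs, k=config.psa_draws, seed=seed)
    evpi_est = evpi_per_patient(psa_res)
    pop = _config_population(config)
    pop_evpi = population_evpi(max(evpi_est.value, 0.0), pop)

    outer = config.outer if outer is None else outer
    inner = config.inner if inner is None else inner
    if evppi_subsets is None:
        evppi_subsets = {"pts_incidence_tailored": list(config.updated_parameters)}
    evppi_ests = {label: evppi(config, specs, subset, outer, inner, seed)
                  for label, subset in evppi_subsets.items()}

    curve = evsi(config, specs, grid=grid, outer=outer, inner=inner, seed=seed)
    curve, optimal_n = enbs(curve, config.trial_fixed_cost, config.trial_cost_per_patient)
    return VOIResult(
        evpi_per_patient=evpi_est,
        effective_population=pop,
        population_evpi=pop_evpi,
        evppi_per_patient=evppi_ests,
        evsi_curve=curve,
        optimal_n=optimal_n,
        settings={"seed": seed, "outer": outer, "inner": inner,
                  "psa_draws": config.psa_draws},
    )
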