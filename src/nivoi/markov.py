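"""Four-state cohort model of post-thrombotic syndrome after deep-vein thrombosis.

States: ``NoPTS -> {MildModPTS, SeverePTS} -> Death``, evaluated as a
discrete-time cohort simulation with two 6-month cycles followed by annual
cycles to a lifetime horizon.  PTS onset can occur only in the first three
cycles (the two years covered by the incidence evidence); PTS states are
chronic (no reversion, no progression between severities); Death is absorbing
and fed by age-dependent background mortality (PTS confers no excess
mortality).

The two strategies differ only in (a) the relative risk multiplying the PTS
onset probabilities after month 6 under individually tailored therapy and
(b) the stocking-wearing schedule, which drives ECS cost and disutility:
under the two-year strategy everyone wears stockings for 24 months, under the
tailored strategy a configured fraction stops after month 6.

Everything here is vectorised over parameter draws; ``run_cohort`` /
``discounted_ce`` expose the single-draw API and ``evaluate_strategies`` the
batch API used by the probabilistic sensitivity analysis, sharing the same
transition and payoff construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import ModelConfig, ParamDraws

__all__ = [
    "STATES",
    "STRATEGIES",
    "CohortTrace",
    "CyclePayoffs",
    "CEOutcome",
    "interval_probs_from_cumulative",
    "apply_rr",
    "build_transitions",
    "run_cohort",
    "build_payoffs",
    "discounted_ce",
    "run_ce",
    "evaluate_strategies",
    "gompertz_intercept",
    "cycle_death_probs",
]

STATES = ("NoPTS", "MildModPTS", "SeverePTS", "Death")
NO_PTS, MILD_PTS, SEVERE_PTS, DEATH = range(4)

STRATEGIES = ("two_year_ecs", "tailored_ecs")
STANDARD, TAILORED = 0, 1

# draw-matrix columns consumed by the engine
_THETA_COLUMNS = (
    "q1", "q2", "q3", "rr_tailored",
    "disutility_mild_pts", "disutility_severe_pts", "disutility_ecs",
    "cost_mild_pts", "cost_severe_pts", "homecare_fraction",
)


# ---------------------------------------------------------------------------
# incidence arithmetic


def interval_probs_from_cumulative(c6, c12, c24):
    """Conditional per-interval onset probabilities from cumulative incidences.

    q1 = c6, q2 = (c12-c6)/(1-c6), q3 = (c24-c12)/(1-c12); the recomposition
    1-(1-q1)(1-q2)(1-q3) returns c24 exactly.
    """
    c6 = np.asarray(c6, dtype=float)
    c12 = np.asarray(c12, dtype=float)
    c24 = np.asarray(c24, dtype=float)
    if np.any(c6 < 0) or np.any(c24 >= 1) or np.any(c12 < c6) or np.any(c24 < c12):
        raise ValueError("cumulative incidences must satisfy 0 <= c6 <= c12 <= c24 < 1")
    q1 = c6
    q2 = (c12 - c6) / (1.0 - c6)
    q3 = (c24 - c12) / (1.0 - c12)
    if q1.ndim == 0:
        return float(q1), float(q2), float(q3)
    return q1, q2, q3


def apply_rr(q2, q3, rr):
    """Scale the post-6-month onset probabilities by a relative risk >= 1.

    The 0-6-month probability is untouched: both strategies are identical
    until the tailoring decision at month 6.  Products are clamped at 1.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1.0):
        raise ValueError("relative risk must be >= 1 (censoring happens upstream)")
    q2p = np.minimum(np.asarray(q2, dtype=float) * rr, 1.0)
    q3p = np.minimum(np.asarray(q3, dtype=float) * rr, 1.0)
    if q2p.ndim == 0:
        return float(q2p), float(q3p)
    return q2p, q3p


# ---------------------------------------------------------------------------
# background mortality


@lru_cache(maxsize=None)
def gompertz_intercept(slope: float, life_expectancy: float) -> float:
    """Gompertz hazard intercept calibrated to a target life expectancy at birth.

    Hazard h(a) = A * exp(slope * a); survival S(a) = exp(-A/b (e^{ba}-1));
    A is solved so that the integral of S equals ``life_expectancy``.
    """
    b = float(slope)

    def e0(a_int: float) -> float:
        surv = lambda t: np.exp(-a_int / b * (np.exp(b * t) - 1.0))
        val, _ = quad(surv, 0.0, 130.0, limit=200)
        return val

    return brentq(lambda a_int: e0(a_int) - life_expectancy, 1e-10, 1e-1, xtol=1e-14)


def cycle_death_probs(config: ModelConfig) -> np.ndarray:
    """Per-cycle background death probability at each cycle's age window.

    An infinite ``life_expectancy`` switches background mortality off
    (useful for analytic checks).
    """
    if not math.isfinite(config.life_expectancy):
        return np.zeros(len(config.cycle_plan))
    a_int = gompertz_intercept(config.gompertz_slope, config.life_expectancy)
    b = config.gompertz_slope
    ages = config.start_age + config.cycle_start_times
    lengths = np.asarray(config.cycle_plan)
    cum_haz = a_int / b * (np.exp(b * (ages + lengths)) - np.exp(b * ages))
    return 1.0 - np.exp(-cum_haz)


# ---------------------------------------------------------------------------
# transitions


def _onset_probs(config: ModelConfig, theta: Mapping[str, np.ndarray], strategy: str,
                 cycle_index: int) -> np.ndarray:
    """PTS onset probability for one cycle (vector over draws)."""
    q1, q2, q3 = (np.asarray(theta[k], dtype=float) for k in ("q1", "q2", "q3"))
    zero = np.zeros(np.broadcast(q1, q2, q3).shape)
    if cycle_index == 0:
        return q1 + zero
    if cycle_index in (1, 2):
        q = (q2, q3)[cycle_index - 1]
        if strategy == STRATEGIES[TAILORED]:
            rr = np.asarray(theta["rr_tailored"], dtype=float)
            return np.minimum(q * rr, 1.0) + zero
        return q + zero
    return zero


def build_transitions(config: ModelConfig, theta: Mapping, strategy: str,
                      cycle_index: int) -> np.ndarray:
    """State-transition matrix (or stack of matrices) for one cycle.

    Within a cycle, background mortality applies first; survivors in NoPTS
    then face the onset probability, split into mild-to-moderate vs severe
    PTS by the configured severity split.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 0 <= cycle_index < len(config.cycle_plan):
        raise ValueError("cycle index outside the cycle plan")
    split = config.severity_split_mild
    theta = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in dict(theta).items()}
    p_on = np.atleast_1d(_onset_probs(config, theta, strategy, cycle_index))
    d = cycle_death_probs(config)[cycle_index]
    k = p_on.shape[0]
    t = np.zeros((k, 4, 4))
    surv = 1.0 - d
    t[:, NO_PTS, NO_PTS] = surv * (1.0 - p_on)
    t[:, NO_PTS, MILD_PTS] = surv * p_on * split
    t[:, NO_PTS, SEVERE_PTS] = surv * p_on * (1.0 - split)
    t[:, NO_PTS, DEATH] = d
    t[:, MILD_PTS, MILD_PTS] = surv
    t[:, MILD_PTS, DEATH] = d
    t[:, SEVERE_PTS, SEVERE_PTS] = surv
    t[:, SEVERE_PTS, DEATH] = d
    t[:, DEATH, DEATH] = 1.0
    return t[0] if k == 1 else t


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortTrace:
    """Cohort occupancy by cycle: row t is the state distribution at the
    start of cycle t; the final row is the distribution at the horizon."""

    occupancy: np.ndarray  # (n_cycles + 1, 4)
    cycle_lengths: np.ndarray
    start_times: np.ndarray
    start_ages: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", np.concatenate(
            (self.start_ages, [self.start_ages[-1] + self.cycle_lengths[-1]])))
        return df


def run_cohort(config: ModelConfig, theta: Mapping, strategy: str) -> CohortTrace:
    """Propagate a full cohort (all starting in NoPTS) through the cycle plan."""
    n_cycles = len(config.cycle_plan)
    occ = np.zeros((n_cycles + 1, 4))
    occ[0, NO_PTS] = 1.0
    for t in range(n_cycles):
        trans = build_transitions(config, theta, strategy, t).reshape(-1, 4, 4)[0]
        occ[t + 1] = occ[t] @ trans
    return CohortTrace(
        occupancy=occ,
        cycle_lengths=np.asarray(config.cycle_plan),
        start_times=config.cycle_start_times,
        start_ages=config.start_age + config.cycle_start_times,
    )


# ---------------------------------------------------------------------------
# payoffs and discounting


def _wear_fraction(config: ModelConfig, strategy: str, cycle_index: int) -> float:
    """Fraction of the alive cohort wearing stockings during a cycle."""
    if cycle_index == 0:
        return 1.0
    if cycle_index in (1, 2):
        if strategy == STRATEGIES[TAILORED]:
            return 1.0 - config.stop_fraction_6mo
        return 1.0
    return 0.0


def _norm_utility(config: ModelConfig, age) -> np.ndarray:
    """Age-dependent population norm utility (linear decline placeholder)."""
    age = np.asarray(age, dtype=float)
    u = config.utility_norm_base - config.utility_norm_slope * np.maximum(
        age - config.utility_norm_ref_age, 0.0)
    return np.clip(u, 0.0, 1.0)


@dataclass(frozen=True)
class CyclePayoffs:
    """Per-cycle, per-state annual cost and utility rates for one strategy."""

    cost_rate: np.ndarray  # (n_cycles, 4), EUR per year of occupancy
    utility_rate: np.ndarray  # (n_cycles, 4), utility weight


@dataclass(frozen=True)
class CEOutcome:
    """Discounted lifetime cost (EUR) and effect (QALY) of one strategy."""

    strategy: str
    cost: float
    qaly: float


def _cycle_rates(config: ModelConfig, theta: Mapping[str, np.ndarray], strategy: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (K, n_cycles, 4) annual cost and utility rates."""
    th = {k: np.atleast_1d(np.asarray(theta[k], dtype=float)) for k in _THETA_COLUMNS}
    k = max(v.shape[0] for v in th.values())
    n_cycles = len(config.cycle_plan)
    ages = config.start_age + config.cycle_start_times
    norm_u = _norm_utility(config, ages)  # (n_cycles,)
    wear = np.array([_wear_fraction(config, strategy, t) for t in range(n_cycles)])

    ecs_rate = config.stocking_cost_per_year + th["homecare_fraction"] * config.homecare_cost_per_year

    cost = np.zeros((k, n_cycles, 4))
    util = np.zeros((k, n_cycles, 4))
    ecs_cycle = ecs_rate[:, None] * wear[None, :]  # (k, n_cycles)
    for state in (NO_PTS, MILD_PTS, SEVERE_PTS):
        cost[:, :, state] = ecs_cycle
    cost[:, :, MILD_PTS] += th["cost_mild_pts"][:, None]
    cost[:, :, SEVERE_PTS] += th["cost_severe_pts"][:, None]

    du_ecs = th["disutility_ecs"][:, None] * wear[None, :]
    util[:, :, NO_PTS] = norm_u[None, :] - du_ecs
    util[:, :, MILD_PTS] = norm_u[None, :] - th["disutility_mild_pts"][:, None] - du_ecs
    util[:, :, SEVERE_PTS] = norm_u[None, :] - th["disutility_severe_pts"][:, None] - du_ecs
    if np.any(util < 0.0):
        warnings.warn("negative state utility clamped to 0", RuntimeWarning, stacklevel=2)
        util = np.clip(util, 0.0, None)
    return cost, util


def build_payoffs(config: ModelConfig, theta: Mapping, strategy: str) -> CyclePayoffs:
    """Single-draw payoff table (annual rates per cycle and state)."""
    cost, util = _cycle_rates(config, theta, strategy)
    return CyclePayoffs(cost_rate=cost[0], utility_rate=util[0])


def discounted_ce(trace: CohortTrace, payoffs: CyclePayoffs, config: ModelConfig,
                  strategy: str = STRATEGIES[STANDARD]) -> CEOutcome:
    """Discounted lifetime cost and QALYs from a trace and payoff table.

    Rewards accrue at the cycle-start state distribution for the cycle's
    length; discount factors use annual compounding evaluated at cycle start
    (no half-cycle correction).
    """
    t0 = trace.start_times
    occ = trace.occupancy[:-1]  # cycle-start rows
    df_c = (1.0 + config.discount_cost) ** (-t0)
    df_e = (1.0 + config.discount_effect) ** (-t0)
    lens = trace.cycle_lengths
    cost = float(np.sum(df_c * lens * np.sum(occ * payoffs.cost_rate, axis=1)))
    qaly = float(np.sum(df_e * lens * np.sum(occ * payoffs.utility_rate, axis=1)))
    return CEOutcome(strategy=strategy, cost=cost, qaly=qaly)


def run_ce(config: ModelConfig, theta: Mapping, strategy: str) -> CEOutcome:
    """Single-draw end-to-end evaluation of one strategy."""
    trace = run_cohort(config, theta, strategy)
    payoffs = build_payoffs(config, theta, strategy)
    return discounted_ce(trace, payoffs, config, strategy)


# ---------------------------------------------------------------------------
# batch evaluation (probabilistic sensitivity analysis back end)


def _theta_arrays(draws) -> dict[str, np.ndarray]:
    if isinstance(draws, ParamDraws):
        draws = draws.values
    if hasattr(draws, "columns"):  # DataFrame
        return {c: draws[c].to_numpy(dtype=float) for c in _THETA_COLUMNS}
    return {c: np.atleast_1d(np.asarray(draws[c], dtype=float)) for c in _THETA_COLUMNS}


def evaluate_strategies(config: ModelConfig, draws,
                        strategies: Sequence[str] = STRATEGIES
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Discounted cost and QALYs for every draw and strategy.

    Parameters
    ----------
    draws
        ParamDraws, DataFrame or mapping with the engine's theta columns.

    Returns
    -------
    costs, qalys : ndarray of shape (K, n_strategies)
    """
    theta = _theta_arrays(draws)
    k = theta["q1"].shape[0]
    n_cycles = len(config.cycle_plan)
    death = cycle_death_probs(config)
    costs = np.zeros((k, len(strategies)))
    qalys = np.zeros((k, len(strategies)))
    t0 = config.cycle_start_times
    lens = np.asarray(config.cycle_plan)
    df_c = (1.0 + config.discount_cost) ** (-t0)
    df_e = (1.0 + config.discount_effect) ** (-t0)
    split = config.severity_split_mild

    for s, strategy in enumerate(strategies):
        cost_rate, util_rate = _cycle_rates(config, theta, strategy)  # (k, C, 4)
        occ = np.zeros((k, 4))
        occ[:, NO_PTS] = 1.0
        acc_cost = np.zeros(k)
        acc_qaly = np.zeros(k)
        for t in range(n_cycles):
            acc_cost += df_c[t] * lens[t] * np.einsum("ki,ki->k", occ, cost_rate[:, t])
            acc_qaly += df_e[t] * lens[t] * np.einsum("ki,ki->k", occ, util_rate[:, t])
            # transition (mortality first, then onset among survivors)
            p_on = _onset_probs(config, theta, strategy, t)
            surv = 1.0 - death[t]
            new = np.empty_like(occ)
            new[:, NO_PTS] = occ[:, NO_PTS] * surv * (1.0 - p_on)
            new[:, MILD_PTS] = occ[:, MILD_PTS] * surv + occ[:, NO_PTS] * surv * p_on * split
            new[:, SEVERE_PTS] = (occ[:, SEVERE_PTS] * surv
                                  + occ[:, NO_PTS] * surv * p_on * (1.0 - split))
            new[:, DEATH] = occ[:, DEATH] + (1.0 - occ[:, DEATH]) * death[t]
            occ = new
        costs[:, s] = acc_cost
        qalys[:, s] = acc_qaly
    return costs, qalys
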