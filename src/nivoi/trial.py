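"""Simulation of hypothetical non-inferiority trials and Bayesian updating.

This is the inner machinery of the expected value of sample information:
given a "true" parameter vector drawn from the priors, a two-arm trial is
simulated (per-arm multinomial counts of PTS onset in the 0-6, 6-12 and
12-24 month intervals), and the simulated counts update the model priors in
closed form:

* the three interval onset probabilities get conjugate Beta-binomial updates
  from the standard arm (those parameters describe standard therapy);
* the log relative risk gets a precision-weighted normal update from the
  two-arm contrast of conditional post-6-month onset proportions — the
  quantity the RR actually multiplies — with a delta-method standard error;
  posterior RR draws are censored at 1 downstream, like the prior.

Trials with a zero cell in either arm's post-6-month event table carry no
usable information for the RR contrast; the prior is kept unchanged and the
event is flagged rather than patched with a continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialDesign",
    "TrialOutcome",
    "Posterior",
    "simulate_trial",
    "update_incidence_posterior",
    "update_rr_posterior",
    "posterior_from_trial",
]


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm trial design: total size, allocation and costs."""

    n_total: int
    allocation_ratio: float = 1.0  # new : standard
    fixed_cost: float = 10_000.0
    cost_per_patient: float = 5_000.0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation_ratio must be > 0")

    @property
    def arm_sizes(self) -> tuple[int, int]:
        """(standard, new) arm sizes; rounding preserves the total."""
        n_std = int(round(self.n_total / (1.0 + self.allocation_ratio)))
        n_std = min(max(n_std, 1), self.n_total - 1)
        return n_std, self.n_total - n_std

    @property
    def cost(self) -> float:
        return self.fixed_cost + self.cost_per_patient * self.n_total


@dataclass(frozen=True)
class TrialOutcome:
    """Per-arm counts: PTS onset in each interval plus PTS-free at 24 months."""

    standard: tuple[int, int, int, int]  # (x1, x2, x3, free)
    tailored: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for arm in (self.standard, self.tailored):
            if any(c < 0 for c in arm):
                raise ValueError("counts must be nonnegative")

    @property
    def arm_sizes(self) -> tuple[int, int]:
        return sum(self.standard), sum(self.tailored)

    def events_24m(self) -> tuple[int, int]:
        """(standard, tailored) counts with PTS onset by 24 months."""
        return sum(self.standard[:3]), sum(self.tailored[:3])


@dataclass(frozen=True)
class Posterior:
    """Closed-form posterior after one simulated trial."""

    q_betas: tuple[tuple[float, float], ...]  # Beta(a,b) for q1,q2,q3
    logrr_mu: float
    logrr_sigma: float
    rr_updated: bool  # False when a zero cell forced keeping the prior


def _interval_cell_probs(q1: float, q2: float, q3: float) -> np.ndarray:
    """Multinomial cell probabilities (onset in each interval, no onset)."""
    p1 = q1
    p2 = (1.0 - q1) * q2
    p3 = (1.0 - q1) * (1.0 - q2) * q3
    p = np.array([p1, p2, p3, 1.0 - p1 - p2 - p3])
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("invalid interval probabilities")
    return np.clip(p, 0.0, 1.0)


def simulate_trial(design: TrialDesign, theta_true, rng: np.random.Generator
                   ) -> TrialOutcome:
    """Simulate one trial under true parameters (q1, q2, q3, rr).

    The standard arm draws from the interval probabilities as given; the
    tailored arm applies the relative risk to the post-6-month intervals
    (clamped at 1), mirroring the decision model.
    """
    q1, q2, q3 = (float(theta_true[k]) for k in ("q1", "q2", "q3"))
    rr = float(theta_true["rr_tailored"])
    n_std, n_new = design.arm_sizes
    p_std = _interval_cell_probs(q1, q2, q3)
    p_new = _interval_cell_probs(q1, min(rr * q2, 1.0), min(rr * q3, 1.0))
    std = rng.multinomial(n_std, p_std)
    new = rng.multinomial(n_new, p_new)
    return TrialOutcome(standard=tuple(int(c) for c in std),
                        tailored=tuple(int(c) for c in new))


def update_incidence_posterior(prior_betas, standard_counts) -> list[tuple[float, float]]:
    """Conjugate Beta updates of the interval onset probabilities.

    Interval i has x_i events among the m_i still at risk (prior-interval
    events leave the risk set): Beta(a_i + x_i, b_i + m_i - x_i).
    """
    x1, x2, x3, free = standard_counts
    m1 = x1 + x2 + x3 + free
    at_risk = (m1, m1 - x1, m1 - x1 - x2)
    out = []
    for (a, b), x, m in zip(prior_betas, (x1, x2, x3), at_risk):
        if x > m or m < 0:
            raise ValueError("event count exceeds at-risk set")
        out.append((a + x, b + (m - x)))
    return out


def update_rr_posterior(prior_mu: float, prior_sigma: float, outcome: TrialOutcome
                        ) -> tuple[float, float, bool]:
    """Precision-weighted normal update of log RR from the post-6-month contrast.

    The RR multiplies the onset probabilities *after* month 6, so the
    identifying data summary is the ratio of conditional onset proportions
    among patients still PTS-free at month 6:
    ``r_hat = (e_new/m_new) / (e_std/m_std)`` with ``e`` the 6-24-month
    events and ``m`` the month-6 risk sets.  (The 24-month *cumulative*
    contrast would be diluted by the shared 0-6-month incidence and leave
    the RR under-identified.)  The delta-method variance of ``log r_hat`` is
    ``(1-p_new)/(m_new p_new) + (1-p_std)/(m_std p_std)``; combining with
    the Normal(prior_mu, prior_sigma^2) prior in precision-weighted form
    gives the posterior.  Requires at least one event and one non-event in
    each arm's post-6-month window; otherwise the prior is returned with
    ``updated=False``.
    """
    e_std = outcome.standard[1] + outcome.standard[2]
    e_new = outcome.tailored[1] + outcome.tailored[2]
    m_std = sum(outcome.standard) - outcome.standard[0]
    m_new = sum(outcome.tailored) - outcome.tailored[0]
    if min(e_std, e_new) < 1 or e_std >= m_std or e_new >= m_new:
        return prior_mu, prior_sigma, False
    p_std = e_std / m_std
    p_new = e_new / m_new
    log_rhat = math.log(p_new / p_std)
    s2 = (1.0 - p_new) / (m_new * p_new) + (1.0 - p_std) / (m_std * p_std)
    post_var = 1.0 / (1.0 / prior_sigma**2 + 1.0 / s2)
    post_mu = post_var * (prior_mu / prior_sigma**2 + log_rhat / s2)
    return post_mu, math.sqrt(post_var), True


def posterior_from_trial(prior_betas, prior_mu: float, prior_sigma: float,
                         outcome: TrialOutcome) -> Posterior:
    """Full closed-form posterior from one simulated trial outcome."""
    q_post = update_incidence_posterior(prior_betas, outcome.standard)
    mu, sigma, updated = update_rr_posterior(prior_mu, prior_sigma, outcome)
    return Posterior(q_betas=tuple(q_post), logrr_mu=mu, logrr_sigma=sigma,
                     rr_updated=updated)
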