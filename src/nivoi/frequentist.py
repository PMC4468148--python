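"""Classic frequentist sample-size calculation and test for non-inferiority.

The Blackwelder design: with success proportions p_S (standard) and p_E
(new therapy), non-inferiority margin delta, one-sided significance level
alpha and power 1-beta, the required size per group is

    n = (z_{1-alpha} + z_{1-beta})^2 (p_S(1-p_S) + p_E(1-p_E)) / (p_S - p_E - delta)^2

rounded up, and the corresponding one-sided z-test concludes non-inferiority
when  z = (p_hat_E - p_hat_S + delta) / SE  exceeds z_{1-alpha}.

"Success" may be coded either as the favourable outcome or its complement;
the binomial variance p(1-p) is identical either way, so the formula is
indifferent to the coding (the test direction is not — p here is the
proportion with the *favourable* outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["NIDesignInputs", "NISampleSize", "NITestResult", "ni_sample_size", "ni_test"]


@dataclass(frozen=True)
class NIDesignInputs:
    """Design parameters of a two-arm non-inferiority trial."""

    p_s: float  # success proportion, standard therapy
    p_e: float  # success proportion, new therapy
    delta: float  # non-inferiority margin (proportion, > 0)
    alpha: float  # one-sided significance level
    power: float  # 1 - beta

    def __post_init__(self) -> None:
        for key in ("p_s", "p_e"):
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{key} must be in (0,1), got {v}")
        if not self.delta > 0.0:
            raise ValueError("delta must be > 0")
        for key in ("alpha", "power"):
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{key} must be in (0,1), got {v}")
        # tolerance catches deficits at the margin up to float rounding
        if self.p_s - self.p_e >= self.delta * (1.0 - 1e-9):
            raise ValueError(
                "no finite sample size: the assumed deficit p_s - p_e reaches the margin"
            )


@dataclass(frozen=True)
class NISampleSize:
    """Sample-size result with all intermediates, for a transparent report.

    ``n_exact`` is the unrounded per-group solution; the default convention
    rounds it up per group and doubles (alternative roundings of the z
    quantiles or inputs can shift the total by a couple of patients).
    """

    n_per_group: int
    n_total: int
    n_exact: float
    z_alpha: float
    z_beta: float
    variance_sum: float
    denominator: float
    rounding: str = "ceil-per-group"


def ni_sample_size(inputs: NIDesignInputs,
                   z_alpha: float | None = None,
                   z_beta: float | None = None) -> NISampleSize:
    """Per-group and total sample size for the non-inferiority design.

    ``z_alpha``/``z_beta`` default to the exact normal quantiles; they can be
    overridden (e.g. with table values) to reproduce published roundings.
    """
    za = norm.ppf(1.0 - inputs.alpha) if z_alpha is None else z_alpha
    zb = norm.ppf(inputs.power) if z_beta is None else z_beta
    var_sum = inputs.p_s * (1.0 - inputs.p_s) + inputs.p_e * (1.0 - inputs.p_e)
    denom = (inputs.p_s - inputs.p_e - inputs.delta) ** 2
    n_exact = (za + zb) ** 2 * var_sum / denom
    n_group = math.ceil(n_exact - 1e-12)
    return NISampleSize(n_per_group=n_group, n_total=2 * n_group, n_exact=n_exact,
                        z_alpha=za, z_beta=zb, variance_sum=var_sum, denominator=denom)


@dataclass(frozen=True)
class NITestResult:
    z: float
    p_value: float  # one-sided
    non_inferior: bool
    se: float


def ni_test(x_s: int, n_s: int, x_e: int, n_e: int, delta: float,
            alpha: float = 0.05) -> NITestResult:
    """One-sided non-inferiority z-test on two success counts.

    ``x``/``n`` are successes (favourable outcomes) and group sizes; the test
    statistic is (p_hat_e - p_hat_s + delta)/SE with the unpooled binomial SE.
    """
    for x, n, lbl in ((x_s, n_s, "standard"), (x_e, n_e, "new")):
        if n < 1 or not 0 <= x <= n:
            raise ValueError(f"invalid counts for {lbl} arm: x={x}, n={n}")
    p_s = x_s / n_s
    p_e = x_e / n_e
    var = p_s * (1.0 - p_s) / n_s + p_e * (1.0 - p_e) / n_e
    if var == 0.0:
        raise ValueError("degenerate data: zero variance in both arms")
    se = math.sqrt(var)
    z = (p_e - p_s + delta) / se
    p_value = float(norm.sf(z))
    return NITestResult(z=z, p_value=p_value, non_inferior=bool(z > norm.ppf(1.0 - alpha)),
                        se=se)
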