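"""Parameter registry: distribution specifications, config loading, prior sampling.

All model inputs are expressed as :class:`ParamSpec` entries — a distribution
family plus the moments (mean, SE) on the natural scale — or as fixed global
settings collected in :class:`ModelConfig`.  Uncertain quantities:

* the cumulative incidence of post-thrombotic syndrome (PTS) at 6, 12 and 24
  months after deep-vein thrombosis (Beta priors fitted by moment matching);
* the relative risk (RR) of PTS onset after month 6 under individually
  tailored elastic-compression-stocking (ECS) therapy, a lognormal prior on
  the RR censored below at 1 ("tailored therapy is at best equal");
* disutilities, annual costs and the home-care fraction (Beta/Gamma priors).

The three cumulative incidences are sampled *jointly monotone*: the registry
converts them to conditional per-interval onset probabilities (q1, q2, q3),
refits independent Beta priors to those by moment matching, samples the
conditionals independently and recomposes the cumulative values — so
c6 <= c12 <= c24 holds in every draw by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import ndtri

from ._streams import stream

__all__ = [
    "ParamSpec",
    "ModelConfig",
    "ParamDraws",
    "CensoredLogNormal",
    "ConfigError",
    "beta_from_moments",
    "gamma_from_moments",
    "censored_lognormal",
    "load_config",
    "default_config_path",
    "sample_priors",
    "conditional_incidence_specs",
    "incidence_prior_betas",
]

FAMILIES = frozenset(
    {"beta-by-moments", "gamma-by-moments", "lognormal-censored", "normal", "fixed"}
)

# parameter names the cohort engine expects in a draw matrix
CUMULATIVE_INCIDENCE_NAMES = ("cum_inc_6m", "cum_inc_12m", "cum_inc_24m")
CONDITIONAL_INCIDENCE_NAMES = ("q1", "q2", "q3")
RR_NAME = "rr_tailored"


class ConfigError(ValueError):
    """Invalid or inconsistent configuration; the message names the key."""


# ---------------------------------------------------------------------------
# moment-matching fits


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a Beta(alpha, beta) distribution to a given mean and standard error.

    Solves the two moment equations exactly: with
    ``v = mean*(1-mean)/se**2 - 1``, ``alpha = mean*v`` and
    ``beta = (1-mean)*v``.

    Raises
    ------
    ConfigError
        If ``mean`` is outside (0, 1) or ``se**2 >= mean*(1-mean)`` (no Beta
        distribution has that much spread at that mean).
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta-by-moments: mean must be in (0,1), got {mean}")
    if se <= 0.0:
        raise ConfigError(f"beta-by-moments: se must be > 0, got {se} (use family=fixed)")
    if se * se >= mean * (1.0 - mean):
        raise ConfigError(
            f"beta-by-moments: infeasible moments, se^2={se*se:.6g} >= "
            f"mean*(1-mean)={mean*(1-mean):.6g}"
        )
    v = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * v, (1.0 - mean) * v


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a Gamma(shape, rate) distribution to a given mean and standard error.

    ``shape = mean**2/se**2``, ``rate = mean/se**2``.
    """
    if mean <= 0.0:
        raise ConfigError(f"gamma-by-moments: mean must be > 0, got {mean}")
    if se <= 0.0:
        raise ConfigError(f"gamma-by-moments: se must be > 0, got {se} (use family=fixed)")
    return mean * mean / (se * se), mean / (se * se)


@dataclass(frozen=True)
class CensoredLogNormal:
    """Lognormal distribution censored (rounded up) below at ``censor_at``.

    Draws are ``max(exp(Z), censor_at)`` with ``Z ~ Normal(mu_log, sigma_log^2)``.
    Used for the relative-risk parameter: exp(Z) with sigma_log = 0.612 puts
    the upper 97.5% quantile at ~3.32, and all mass below 1 is moved to 1.
    """

    sigma_log: float
    mu_log: float = 0.0
    censor_at: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0.0:
            raise ConfigError(f"lognormal-censored: sigma_log must be > 0, got {self.sigma_log}")
        if self.censor_at <= 0.0:
            raise ConfigError("lognormal-censored: censor_at must be > 0")

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.normal(self.mu_log, self.sigma_log, size=k)
        return np.maximum(np.exp(z), self.censor_at)

    def quantile(self, q):
        """Quantile function; equals ``censor_at`` for q below the censored mass."""
        q = np.asarray(q, dtype=float)
        x = np.exp(self.mu_log + self.sigma_log * ndtri(q))
        out = np.maximum(x, self.censor_at)
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        """Closed-form mean  c*Phi((ln c - mu)/s) + e^{mu+s^2/2}*Phi((mu+s^2-ln c)/s)."""
        from scipy.stats import norm as _norm

        c, mu, s = self.censor_at, self.mu_log, self.sigma_log
        lc = math.log(c)
        return c * _norm.cdf((lc - mu) / s) + math.exp(mu + s * s / 2.0) * _norm.cdf(
            (mu + s * s - lc) / s
        )


def censored_lognormal(sigma_log: float, censor_at: float = 1.0) -> CensoredLogNormal:
    """Construct the censored-lognormal distribution handle."""
    return CensoredLogNormal(sigma_log=sigma_log, censor_at=censor_at)


# ---------------------------------------------------------------------------
# parameter specifications


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain (or fixed) model parameter.

    ``family`` selects how the natural-scale moments are turned into a
    sampling distribution.  ``appendix_default`` flags quantities whose values
    are documented placeholders rather than sourced estimates.
    """

    name: str
    family: str
    mean: float = math.nan
    se: float = 0.0
    sigma_log: float = math.nan  # lognormal-censored only
    censor_at: float = 1.0
    lower: float | None = None
    upper: float | None = None
    units: str = ""
    appendix_default: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"parameter {self.name!r}: unknown family {self.family!r}")
        if self.family == "beta-by-moments":
            beta_from_moments(self.mean, self.se)  # validates
        elif self.family == "gamma-by-moments":
            gamma_from_moments(self.mean, self.se)
        elif self.family == "lognormal-censored":
            if not self.sigma_log > 0.0:
                raise ConfigError(
                    f"parameter {self.name!r}: lognormal-censored requires sigma_log > 0"
                )
        elif self.family == "normal":
            if not self.se > 0.0:
                raise ConfigError(f"parameter {self.name!r}: normal requires se > 0")
        elif self.family == "fixed":
            if self.se != 0.0:
                raise ConfigError(f"parameter {self.name!r}: fixed requires se = 0")
            if not math.isfinite(self.mean):
                raise ConfigError(f"parameter {self.name!r}: fixed requires a mean value")

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "beta-by-moments":
            a, b = beta_from_moments(self.mean, self.se)
            x = rng.beta(a, b, size=k)
        elif self.family == "gamma-by-moments":
            shape, rate = gamma_from_moments(self.mean, self.se)
            x = rng.gamma(shape, 1.0 / rate, size=k)
        elif self.family == "lognormal-censored":
            x = CensoredLogNormal(self.sigma_log, censor_at=self.censor_at).sample(k, rng)
        elif self.family == "normal":
            x = rng.normal(self.mean, self.se, size=k)
        else:  # fixed
            x = np.full(k, self.mean)
        if self.lower is not None:
            x = np.maximum(x, self.lower)
        if self.upper is not None:
            x = np.minimum(x, self.upper)
        return x

    @property
    def variance(self) -> float:
        if self.family == "lognormal-censored":
            d = CensoredLogNormal(self.sigma_log, censor_at=self.censor_at)
            # second moment of max(e^Z, c) via the same censoring identity
            two = CensoredLogNormal(2.0 * self.sigma_log, mu_log=2.0 * d.mu_log,
                                    censor_at=d.censor_at ** 2).mean()
            return two - d.mean() ** 2
        return self.se * self.se


# ---------------------------------------------------------------------------
# global settings


@dataclass(frozen=True)
class ModelConfig:
    """Fixed global settings of the decision model, population and trial."""

    # decision model
    threshold: float  # willingness to pay, EUR per QALY
    discount_cost: float  # annual rate
    discount_effect: float  # annual rate
    start_age: float  # years at DVT
    max_age: float  # lifetime horizon cap
    severity_split_mild: float  # share of PTS onsets that are mild-to-moderate
    stop_fraction_6mo: float  # tailored arm: fraction stopping ECS at month 6
    stocking_cost_per_year: float  # EUR per wearer-year
    homecare_cost_per_year: float  # EUR per year for patients needing home care
    gompertz_slope: float  # background-mortality log-hazard slope per year
    life_expectancy: float  # calibration target for the mortality intercept
    utility_norm_base: float  # population norm utility at/below the reference age
    utility_norm_slope: float  # utility decline per year above the reference age
    utility_norm_ref_age: float
    # effective population
    annual_incidence: float  # patients per year affected by the decision
    tech_lifetime: float  # years the technology decision stays relevant
    population_discount_rate: float
    discount_population: bool
    # trial
    trial_fixed_cost: float
    trial_cost_per_patient: float
    allocation_ratio: float
    # value-of-information settings
    sample_size_grid: tuple[int, ...]
    outer: int
    inner: int
    psa_draws: int
    updated_parameters: tuple[str, ...]

    def __post_init__(self) -> None:
        for key in ("discount_cost", "discount_effect", "population_discount_rate"):
            r = getattr(self, key)
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"{key}: rate must be in [0,1), got {r}")
        for key in ("severity_split_mild", "stop_fraction_6mo"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}: must be in [0,1], got {v}")
        if self.max_age <= self.start_age:
            raise ConfigError("max_age: must exceed start_age")
        if self.threshold < 0:
            raise ConfigError("threshold: must be >= 0")
        grid = tuple(self.sample_size_grid)
        if (
            not grid
            or any(int(n) != n or n <= 0 for n in grid)
            or any(b <= a for a, b in zip(grid, grid[1:]))
        ):
            raise ConfigError("sample_size_grid: must be strictly increasing positive integers")

    @property
    def cycle_plan(self) -> tuple[float, ...]:
        """Cycle lengths in years: two 6-month cycles, then annual to max_age."""
        n_annual = int(round(self.max_age - self.start_age - 1.0))
        return (0.5, 0.5) + (1.0,) * n_annual

    @property
    def horizon(self) -> float:
        return float(sum(self.cycle_plan))

    @property
    def cycle_start_times(self) -> np.ndarray:
        plan = np.asarray(self.cycle_plan)
        return np.concatenate(([0.0], np.cumsum(plan)[:-1]))


@dataclass(frozen=True)
class ParamDraws:
    """K joint draws of the parameter vector theta, one column per parameter."""

    values: "object"  # pandas.DataFrame
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.values)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration file


_MODEL_KEYS = {
    "threshold", "discount_cost", "discount_effect", "start_age", "max_age",
    "severity_split_mild", "stop_fraction_6mo", "stocking_cost_per_year",
    "homecare_cost_per_year", "gompertz_slope", "life_expectancy",
    "utility_norm_base", "utility_norm_slope", "utility_norm_ref_age",
}
_POPULATION_KEYS = {
    "annual_incidence", "tech_lifetime", "population_discount_rate", "discount_population",
}
_TRIAL_KEYS = {"fixed_cost", "cost_per_patient", "allocation_ratio"}
_VOI_KEYS = {"sample_size_grid", "outer", "inner", "psa_draws", "updated_parameters"}
_PARAM_KEYS = {
    "name", "family", "mean", "se", "sigma_log", "censor_at", "lower", "upper",
    "units", "appendix_default",
}


def default_config_path() -> Path:
    """Path of the packaged case-study configuration."""
    return Path(__file__).parent / "data" / "case_study.yaml"


def _section(raw: dict, name: str, allowed: set[str]) -> dict:
    if name not in raw:
        raise ConfigError(f"missing section {name!r}")
    sec = raw[name]
    if not isinstance(sec, dict) and name != "parameters":
        raise ConfigError(f"section {name!r} must be a mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ConfigError(f"section {name!r}: unknown keys {sorted(unknown)}")
    missing = allowed - set(sec)
    if missing:
        raise ConfigError(f"section {name!r}: missing keys {sorted(missing)}")
    return sec


def load_config(path=None) -> tuple[ModelConfig, list[ParamSpec]]:
    """Load and validate a YAML configuration.

    Parsing is strict: every key is mandatory and unknown keys are rejected,
    so a typo fails loudly instead of silently falling back to a default.
    """
    path = Path(path) if path is not None else default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"model", "population", "trial", "voi", "parameters"}
    if unknown:
        raise ConfigError(f"unknown top-level sections {sorted(unknown)}")

    model = _section(raw, "model", _MODEL_KEYS)
    pop = _section(raw, "population", _POPULATION_KEYS)
    trial = _section(raw, "trial", _TRIAL_KEYS)
    voi = _section(raw, "voi", _VOI_KEYS)

    if "parameters" not in raw or not isinstance(raw["parameters"], list):
        raise ConfigError("missing section 'parameters' (a list)")
    specs: list[ParamSpec] = []
    for entry in raw["parameters"]:
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError("each parameter entry must be a mapping with a 'name'")
        unknown = set(entry) - _PARAM_KEYS
        if unknown:
            raise ConfigError(f"parameter {entry.get('name')!r}: unknown keys {sorted(unknown)}")
        specs.append(ParamSpec(**entry))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate parameter names")
    for required in CUMULATIVE_INCIDENCE_NAMES + (RR_NAME,):
        if required not in names:
            raise ConfigError(f"missing mandatory parameter {required!r}")

    cfg = ModelConfig(
        threshold=float(model["threshold"]),
        discount_cost=float(model["discount_cost"]),
        discount_effect=float(model["discount_effect"]),
        start_age=float(model["start_age"]),
        max_age=float(model["max_age"]),
        severity_split_mild=float(model["severity_split_mild"]),
        stop_fraction_6mo=float(model["stop_fraction_6mo"]),
        stocking_cost_per_year=float(model["stocking_cost_per_year"]),
        homecare_cost_per_year=float(model["homecare_cost_per_year"]),
        gompertz_slope=float(model["gompertz_slope"]),
        life_expectancy=float(model["life_expectancy"]),
        utility_norm_base=float(model["utility_norm_base"]),
        utility_norm_slope=float(model["utility_norm_slope"]),
        utility_norm_ref_age=float(model["utility_norm_ref_age"]),
        annual_incidence=float(pop["annual_incidence"]),
        tech_lifetime=float(pop["tech_lifetime"]),
        population_discount_rate=float(pop["population_discount_rate"]),
        discount_population=bool(pop["discount_population"]),
        trial_fixed_cost=float(trial["fixed_cost"]),
        trial_cost_per_patient=float(trial["cost_per_patient"]),
        allocation_ratio=float(trial["allocation_ratio"]),
        sample_size_grid=tuple(int(n) for n in voi["sample_size_grid"]),
        outer=int(voi["outer"]),
        inner=int(voi["inner"]),
        psa_draws=int(voi["psa_draws"]),
        updated_parameters=tuple(voi["updated_parameters"]),
    )
    return cfg, specs


# ---------------------------------------------------------------------------
# joint incidence handling and prior sampling


def conditional_incidence_specs(specs: Sequence[ParamSpec]) -> list[ParamSpec]:
    """Beta specs for the conditional per-interval onset probabilities q1,q2,q3.

    The source evidence reports *cumulative* incidences c6 <= c12 <= c24 with
    standard errors from one follow-up cohort.  We back out an effective
    cohort size N from the 6-month estimate, N = c6(1-c6)/se6^2, take the
    conditional probabilities q1 = c6, q2 = (c12-c6)/(1-c6),
    q3 = (c24-c12)/(1-c12), and give each a binomial standard error on its
    own at-risk set (N, N(1-c6), N(1-c12)).  This keeps the three priors
    independent while matching the within-cohort information content.
    """
    by_name = {s.name: s for s in specs}
    c6s, c12s, c24s = (by_name[n] for n in CUMULATIVE_INCIDENCE_NAMES)
    c6, c12, c24 = c6s.mean, c12s.mean, c24s.mean
    if not 0.0 <= c6 <= c12 <= c24 < 1.0:
        raise ConfigError("cumulative incidences must satisfy 0 <= c6 <= c12 <= c24 < 1")
    from .markov import interval_probs_from_cumulative

    q1, q2, q3 = interval_probs_from_cumulative(c6, c12, c24)
    families = {s.family for s in (c6s, c12s, c24s)}
    if families == {"fixed"}:
        return [ParamSpec(name=n, family="fixed", mean=q, units="probability")
                for n, q in zip(CONDITIONAL_INCIDENCE_NAMES, (q1, q2, q3))]
    if "fixed" in families:
        raise ConfigError("cumulative incidences must be all uncertain or all fixed")
    n_eff = c6 * (1.0 - c6) / (c6s.se * c6s.se)
    at_risk = (n_eff, n_eff * (1.0 - c6), n_eff * (1.0 - c12))
    out = []
    for name, q, m in zip(CONDITIONAL_INCIDENCE_NAMES, (q1, q2, q3), at_risk):
        se = math.sqrt(q * (1.0 - q) / m)
        out.append(ParamSpec(name=name, family="beta-by-moments", mean=q, se=se,
                             units="probability"))
    return out


def incidence_prior_betas(specs: Sequence[ParamSpec]) -> list[tuple[float, float]]:
    """Prior Beta(alpha, beta) parameters of (q1, q2, q3)."""
    return [beta_from_moments(s.mean, s.se) for s in conditional_incidence_specs(specs)]


def sample_priors(
    specs: Sequence[ParamSpec],
    k: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ParamDraws:
    """Draw K joint samples of the parameter vector from the priors.

    All parameters are independent except the incidence triplet, which is
    sampled through its conditional decomposition (see
    :func:`conditional_incidence_specs`) and recomposed, guaranteeing
    c6 <= c12 <= c24 in every draw.  The draw matrix carries both the
    conditional columns (q1,q2,q3 — what the cohort engine consumes) and the
    recomposed cumulative columns.
    """
    import pandas as pd

    if k < 1:
        raise ValueError("k must be >= 1")
    if rng is None:
        rng = stream(0 if seed is None else seed, "psa")
    cols: dict[str, np.ndarray] = {}
    q_specs = conditional_incidence_specs(specs)
    qs = [s.sample(k, rng) for s in q_specs]
    cols["q1"], cols["q2"], cols["q3"] = qs
    cols["cum_inc_6m"] = qs[0]
    cols["cum_inc_12m"] = 1.0 - (1.0 - qs[0]) * (1.0 - qs[1])
    cols["cum_inc_24m"] = 1.0 - (1.0 - qs[0]) * (1.0 - qs[1]) * (1.0 - qs[2])
    for s in specs:
        if s.name in CUMULATIVE_INCIDENCE_NAMES:
            continue
        cols[s.name] = s.sample(k, rng)
    return ParamDraws(values=pd.DataFrame(cols), seed=seed)
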