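"""Probabilistic sensitivity analysis (PSA) and net monetary benefit (NMB).

Each PSA draw evaluates *both* strategies at the same parameter vector
(common random parameters), which maximises the precision of incremental
comparisons and is what the value-of-information analysis requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov
from ._streams import stream
from .params import ModelConfig, ParamDraws, ParamSpec, sample_priors

__all__ = ["PSAResult", "nmb", "run_psa", "summarize_psa"]


def nmb(ce, threshold: float) -> float:
    """Net monetary benefit of one strategy: threshold * QALY - cost (EUR)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * ce.qaly - ce.cost


@dataclass(frozen=True)
class PSAResult:
    """Per-draw costs, QALYs and NMB for each strategy (columns follow
    ``strategies``; column 0 is the standard two-year strategy)."""

    costs: np.ndarray  # (K, S)
    qalys: np.ndarray  # (K, S)
    nmb: np.ndarray  # (K, S)
    strategies: tuple[str, ...]
    threshold: float
    seed: int | None
    draws: ParamDraws | None = None

    @property
    def k(self) -> int:
        return self.nmb.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: theta columns plus cost/QALY/NMB per strategy
        (the interchange format consumed downstream)."""
        parts = [] if self.draws is None else [self.draws.values.reset_index(drop=True)]
        for name, arr in (("cost", self.costs), ("qaly", self.qalys), ("nmb", self.nmb)):
            parts.append(pd.DataFrame(
                {f"{name}_{s}": arr[:, j] for j, s in enumerate(self.strategies)}))
        return pd.concat(parts, axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_psa(config: ModelConfig, specs: list[ParamSpec], k: int,
            seed: int | None = None, rng: np.random.Generator | None = None,
            draws: ParamDraws | None = None) -> PSAResult:
    """Propagate K joint prior draws through the cohort model.

    A pre-sampled ``draws`` matrix may be supplied (e.g. posterior draws in
    the EVSI inner loop); otherwise priors are sampled from ``specs``.
    """
    if k < 2 and draws is None:
        raise ValueError("k must be >= 2")
    if draws is None:
        if rng is None:
            rng = stream(0 if seed is None else seed, "psa")
        draws = sample_priors(specs, k, seed=seed, rng=rng)
    costs, qalys = markov.evaluate_strategies(config, draws)
    nmb_mat = config.threshold * qalys - costs
    return PSAResult(costs=costs, qalys=qalys, nmb=nmb_mat,
                     strategies=markov.STRATEGIES, threshold=config.threshold,
                     seed=seed, draws=draws)


def prob_best(nmb_mat: np.ndarray) -> np.ndarray:
    """Probability each strategy has the highest NMB; exact ties share their
    weight equally (zero-probability events under continuous draws)."""
    best = nmb_mat.max(axis=1, keepdims=True)
    is_best = (nmb_mat == best).astype(float)
    return (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)


def summarize_psa(result: PSAResult) -> pd.DataFrame:
    """Mean and empirical 2.5/97.5 percentiles per strategy, plus P(best).

    Percentiles use linear interpolation of the empirical distribution.
    """
    if result.k < 40:
        raise ValueError("need K >= 40 draws for stable percentiles")
    p_best = prob_best(result.nmb)
    rows = []
    for j, s in enumerate(result.strategies):
        row: dict[str, float | str] = {"strategy": s}
        for name, arr in (("cost", result.costs), ("qaly", result.qalys),
                          ("nmb", result.nmb)):
            col = arr[:, j]
            row[f"{name}_mean"] = float(col.mean())
            lo, hi = np.percentile(col, [2.5, 97.5])
            row[f"{name}_p2.5"] = float(lo)
            row[f"{name}_p97.5"] = float(hi)
        row["p_best"] = float(p_best[j])
        rows.append(row)
    return pd.DataFrame(rows)
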