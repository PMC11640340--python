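"""Posterior coefficient summaries: odds ratios, credible intervals, p_d.

The probability of direction (p_d, also called the maximum probability of
effect) is the share of the posterior lying on the same side of zero as
the posterior median — a Bayesian analogue of a one-sided p-value,
ranging from 50% (no directional information) to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = ["CoefficientSummary", "probability_of_direction", "summarize_coefficients"]


@dataclass(frozen=True)
class CoefficientSummary:
    """One row of the model summary table (odds-ratio scale)."""

    term: str
    or_median: float
    ci_low: float
    ci_high: float
    p_d: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_median <= self.ci_high):
            raise ValueError(f"interval must bracket the point estimate for {self.term!r}")
        if not 0.5 <= self.p_d <= 1.0:
            raise ValueError(f"p_d must lie in [0.5, 1], got {self.p_d}")


def probability_of_direction(draws: np.ndarray) -> float:
    """Fraction of draws sharing the sign of the posterior median.

    Draws exactly at zero count half toward agreement; a median of exactly
    zero reports the uninformative value 0.5.  The result is floored at
    0.5 so finite-sample granularity cannot push it below the
    theoretical lower bound.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("cannot compute p_d from an empty sample")
    med = np.median(draws)
    if med == 0.0:
        return 0.5
    sign = np.sign(med)
    agree = np.sum(np.sign(draws) == sign) + 0.5 * np.sum(draws == 0.0)
    return float(max(agree / draws.size, 0.5))


def summarize_coefficients(
    draws: PosteriorDraws,
    level: float = 0.95,
    point: str = "median",
) -> list[CoefficientSummary]:
    """Per-term odds ratio, credible interval and p_d, pooled over chains.

    The odds-ratio point estimate is ``exp(median(beta))`` by default
    (invariant under the log transform); ``point="mean"`` reports the
    posterior mean of ``exp(beta)`` instead.  Interval endpoints are
    linearly interpolated empirical percentiles (type-7).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    alpha = (1.0 - level) / 2.0
    pooled = draws.pooled()
    out = []
    for i, term in enumerate(draws.term_names):
        b = pooled[:, i]
        if point == "median":
            estimate = float(np.exp(np.median(b)))
        else:
            estimate = float(np.mean(np.exp(b)))
        lo, hi = np.exp(np.quantile(b, [alpha, 1.0 - alpha]))
        out.append(
            CoefficientSummary(
                term=term,
                or_median=estimate,
                ci_low=float(lo),
                ci_high=float(hi),
                p_d=probability_of_direction(b),
            )
        )
    return out


def summary_table(summaries: list[CoefficientSummary]) -> pd.DataFrame:
    """Summaries as a tidy table with p_d in percent."""
    return pd.DataFrame(
        {
            "term": [s.term for s in summaries],
            "or": [s.or_median for s in summaries],
            "ci_low": [s.ci_low for s in summaries],
            "ci_high": [s.ci_high for s in summaries],
            "pd_percent": [100.0 * s.p_d for s in summaries],
        }
    )
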