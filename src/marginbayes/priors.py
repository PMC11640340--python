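"""Prior construction for the log-odds coefficients.

Three prior regimes are supported:

* **Weakly informative** — each coefficient gets a ``normal(0, 2.5/s_x)``
  prior, where ``s_x`` is the sample standard deviation of the predictor.
  The scale adapts to the units of the data while staying vague.
* **Informative (elicited)** — a normal is fitted to literature-derived
  0.025/0.5/0.975 quantiles of the log-odds effect by least squares on
  the cumulative distribution function (SHELF-style elicitation).
* **Power-prior discounted** — the informative prior's variance is
  inflated by ``(1 + delta)``, down-weighting the historical evidence;
  ``delta = 0.5`` increases the prior variance by 50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort

__all__ = [
    "NormalPrior",
    "ElicitedQuantiles",
    "PriorSpec",
    "weakly_informative_prior",
    "elicit_normal_from_quantiles",
    "apply_power_prior",
    "read_evidence",
    "elicited_prior",
]

INTERCEPT_TERM = "intercept"
#: Default prior scale for the intercept (log-odds); vague on purpose.
DEFAULT_INTERCEPT_SCALE = 10.0


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior on a log-odds coefficient."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"prior scale must be > 0, got {self.scale}")

    @property
    def variance(self) -> float:
        return self.scale**2


@dataclass(frozen=True)
class ElicitedQuantiles:
    """0.025/0.5/0.975 quantiles of a log-odds effect from the literature."""

    q025: float
    q500: float
    q975: float

    def __post_init__(self) -> None:
        if not self.q025 < self.q500 < self.q975:
            raise ValueError(
                "elicited quantiles must be strictly increasing, got "
                f"({self.q025}, {self.q500}, {self.q975})"
            )

    @classmethod
    def from_odds_ratio(cls, or_low: float, or_med: float, or_high: float) -> "ElicitedQuantiles":
        """Build from an odds ratio with its 95% CI (log-transforms)."""
        if min(or_low, or_med, or_high) <= 0:
            raise ValueError("odds ratios must be positive")
        return cls(float(np.log(or_low)), float(np.log(or_med)), float(np.log(or_high)))


@dataclass(frozen=True)
class PriorSpec:
    """Per-term normal priors for the full model (intercept + covariates).

    ``provenance`` tags each term as ``weak``, ``elicited`` or
    ``discounted``; ``delta`` records the discounting factor when set.
    """

    priors: dict[str, NormalPrior]
    provenance: dict[str, str]
    delta: float | None = None

    def __post_init__(self) -> None:
        if set(self.priors) != set(self.provenance):
            raise ValueError("provenance must tag exactly the prior terms")

    @property
    def terms(self) -> list[str]:
        return list(self.priors)

    def locations(self, order: list[str]) -> np.ndarray:
        return np.array([self.priors[t].location for t in order])

    def scales(self, order: list[str]) -> np.ndarray:
        return np.array([self.priors[t].scale for t in order])

    def to_json(self, path) -> None:
        rows = [
            {
                "term": t,
                "location": p.location,
                "scale": p.scale,
                "provenance": self.provenance[t],
                "delta": self.delta,
            }
            for t, p in self.priors.items()
        ]
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PriorSpec":
        with open(path) as fh:
            rows = json.load(fh)
        priors = {r["term"]: NormalPrior(r["location"], r["scale"]) for r in rows}
        prov = {r["term"]: r["provenance"] for r in rows}
        deltas = {r["delta"] for r in rows}
        delta = deltas.pop() if len(deltas) == 1 else None
        return cls(priors, prov, delta)


def weakly_informative_prior(
    cohort: Cohort, intercept_scale: float = DEFAULT_INTERCEPT_SCALE
) -> PriorSpec:
    """``normal(0, 2.5/s_x)`` prior per coefficient.

    Scaling by the predictor's sample SD keeps the prior vague in any
    units: the implied prior on the standardized coefficient always has
    scale 2.5.  Raises if any covariate is constant.
    """
    priors = {INTERCEPT_TERM: NormalPrior(0.0, intercept_scale)}
    prov = {INTERCEPT_TERM: "weak"}
    for name, s in cohort.covariate_sd.items():
        if not s > 0:
            raise ValueError(
                f"covariate {name!r} is constant (sd=0); cannot scale its prior"
            )
        priors[name] = NormalPrior(0.0, 2.5 / s)
        prov[name] = "weak"
    return PriorSpec(priors, prov)


def elicit_normal_from_quantiles(
    q: ElicitedQuantiles, tol: float = 1e-12
) -> NormalPrior:
    """Fit a normal to elicited quantiles by least squares on the CDF.

    Minimizes ``sum_i (Phi((q_i - mu)/sigma) - p_i)^2`` over (mu, sigma)
    for p = (0.025, 0.5, 0.975), starting from the moment-based values
    ``mu0 = q500``, ``sigma0 = (q975 - q025)/3.92``.  For quantiles
    generated exactly by a normal the fit recovers it to optimizer
    tolerance.
    """
    probs = np.array([0.025, 0.5, 0.975])
    qs = np.array([q.q025, q.q500, q.q975])
    z = stats.norm.ppf(0.975)
    mu0 = q.q500
    sigma0 = (q.q975 - q.q025) / (2 * z)

    def objective(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        cdf = stats.norm.cdf(qs, loc=mu, scale=np.exp(log_sigma))
        return float(np.sum((cdf - probs) ** 2))

    res = optimize.minimize(
        objective,
        x0=np.array([mu0, np.log(sigma0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": tol, "maxiter": 5000},
    )
    if not res.success:  # pragma: no cover - smooth 2-parameter objective
        raise RuntimeError(f"quantile elicitation failed to converge: {res.message}")
    mu, log_sigma = res.x
    return NormalPrior(float(mu), float(np.exp(log_sigma)))


def apply_power_prior(
    base: PriorSpec,
    delta: float,
    discount_on: str = "variance",
    zero_location: bool = False,
    discount_intercept: bool = False,
) -> PriorSpec:
    """Discount an informative prior by a factor ``delta``.

    Default semantics inflate each coefficient's prior VARIANCE by
    ``(1 + delta)`` while retaining the elicited location — at
    ``delta = 0.5`` the prior variance grows by exactly 50%.
    ``discount_on="scale"`` multiplies the standard deviation by
    ``(1 + delta)`` instead; ``zero_location=True`` additionally recenters
    the discounted priors at zero.  The intercept prior is left untouched
    unless ``discount_intercept`` is set.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    if discount_on not in ("variance", "scale"):
        raise ValueError(f"discount_on must be 'variance' or 'scale', got {discount_on!r}")
    factor = np.sqrt(1.0 + delta) if discount_on == "variance" else 1.0 + delta
    priors: dict[str, NormalPrior] = {}
    prov: dict[str, str] = {}
    for term, p in base.priors.items():
        if term == INTERCEPT_TERM and not discount_intercept:
            priors[term] = p
            prov[term] = base.provenance[term]
            continue
        loc = 0.0 if zero_location else p.location
        priors[term] = NormalPrior(loc, p.scale * factor)
        prov[term] = "discounted"
    return PriorSpec(priors, prov, delta=delta)


def read_evidence(path) -> dict[str, ElicitedQuantiles]:
    """Read a literature-evidence CSV into per-predictor quantiles.

    Accepts either log-odds columns (``q025_logodds``, ``q500_logodds``,
    ``q975_logodds``) or odds-ratio columns (``or_low``, ``or_med``,
    ``or_high``), which are log-transformed.
    """
    df = pd.read_csv(path)
    if "predictor" not in df.columns:
        raise ValueError("evidence CSV must have a 'predictor' column")
    logodds_cols = ["q025_logodds", "q500_logodds", "q975_logodds"]
    or_cols = ["or_low", "or_med", "or_high"]
    out: dict[str, ElicitedQuantiles] = {}
    if all(c in df.columns for c in logodds_cols):
        for _, row in df.iterrows():
            out[row["predictor"]] = ElicitedQuantiles(*(float(row[c]) for c in logodds_cols))
    elif all(c in df.columns for c in or_cols):
        for _, row in df.iterrows():
            out[row["predictor"]] = ElicitedQuantiles.from_odds_ratio(
                *(float(row[c]) for c in or_cols)
            )
    else:
        raise ValueError(
            f"evidence CSV needs columns {logodds_cols} or {or_cols}, got {list(df.columns)}"
        )
    return out


def elicited_prior(
    evidence: dict[str, ElicitedQuantiles],
    covariates: list[str] | tuple[str, ...],
    intercept_scale: float = DEFAULT_INTERCEPT_SCALE,
    fallback: PriorSpec | None = None,
) -> PriorSpec:
    """Informative PriorSpec from per-predictor elicited quantiles.

    Covariates missing from the evidence fall back to the matching term of
    ``fallback`` (typically the weakly informative spec) when provided.
    """
    priors = {INTERCEPT_TERM: NormalPrior(0.0, intercept_scale)}
    prov = {INTERCEPT_TERM: "weak"}
    for name in covariates:
        if name in evidence:
            priors[name] = elicit_normal_from_quantiles(evidence[name])
            prov[name] = "elicited"
        elif fallback is not None and name in fallback.priors:
            priors[name] = replace(fallback.priors[name])
            prov[name] = fallback.provenance[name]
        else:
            raise ValueError(f"no elicited evidence or fallback prior for {name!r}")
    return PriorSpec(priors, prov)
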