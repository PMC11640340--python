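"""Cohort container and covariate specifications.

A cohort is a patient table with a binary resection-margin outcome
(``r1``: 1 = microscopically positive margin, 0 = clear margins) and the
eight preoperative predictors entering the risk model: age, ASA physical
status 3-4, arterial involvement, post-neoadjuvant tumor diameter, venous
contact, tumor location in the pancreatic body, preoperative radiotherapy,
and normal preoperative CA19-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for the model covariates.
MODEL_COVARIATES: tuple[str, ...] = (
    "age_years",
    "asa_34",
    "arterial_involvement",
    "post_nat_size_mm",
    "venous_contact",
    "body_location",
    "preop_radiotherapy",
    "ca199_normal",
)

OUTCOME_COLUMN = "r1"


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate.

    Parameters
    ----------
    name : str
        Column label.
    kind : {"continuous", "binary"}
    location : float
        Mean (continuous) or prevalence in [0, 1] (binary).
    scale : float, optional
        Standard deviation; required for continuous covariates.
    lower, upper : float, optional
        Truncation bounds for continuous covariates (plausibility limits).
    transform_note : str
        Free-text units note, e.g. ``"mm"`` or ``"years"``.
    """

    name: str
    kind: str
    location: float
    scale: float | None = None
    lower: float = -np.inf
    upper: float = np.inf
    transform_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 <= self.location <= 1.0:
            raise ValueError(
                f"prevalence for {self.name!r} must be in [0, 1], got {self.location}"
            )
        if self.kind == "continuous":
            if self.scale is None or self.scale <= 0:
                raise ValueError(f"continuous covariate {self.name!r} needs scale > 0")


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth logistic model used to simulate outcomes.

    ``beta`` holds per-covariate log-odds effects; ``exp(beta)`` are the
    odds ratios the simulation encodes.
    """

    intercept: float
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for name, b in self.beta.items():
            if not np.isfinite(b):
                raise ValueError(f"beta for {name!r} must be finite")

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.beta.items()}


class Cohort:
    """Patient table with covariates and a binary R1 outcome.

    Wraps a :class:`pandas.DataFrame`; exposes the design matrix, the
    outcome vector and the per-covariate sample standard deviations used
    for prior scaling.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: tuple[str, ...] | list[str] = MODEL_COVARIATES,
        outcome: str = OUTCOME_COLUMN,
    ):
        missing = [c for c in (*covariates, outcome) if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        if len(data) < 1:
            raise ValueError("cohort must contain at least one subject")
        y = data[outcome]
        valid = y.dropna().isin([0, 1])
        if not valid.all():
            bad = sorted(set(y.dropna()[~valid]))
            raise ValueError(f"outcome column {outcome!r} must be binary 0/1, found {bad}")
        self.data = data.reset_index(drop=True)
        self.covariate_names = tuple(covariates)
        self.outcome_name = outcome

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[list(self.covariate_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome_name].to_numpy(dtype=float)

    @property
    def covariate_sd(self) -> dict[str, float]:
        """Per-covariate sample standard deviation (ddof=1)."""
        out = {}
        for name in self.covariate_names:
            s = float(self.data[name].std(ddof=1)) if self.n > 1 else 0.0
            out[name] = s
        return out

    def complete_cases(self) -> "Cohort":
        cols = [*self.covariate_names, self.outcome_name]
        kept = self.data.dropna(subset=cols)
        if len(kept) == 0:
            raise ValueError("no complete cases for the model covariates")
        return Cohort(kept, self.covariate_names, self.outcome_name)

    @property
    def prevalence(self) -> float:
        return float(np.nanmean(self.y))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Cohort(n={self.n}, covariates={len(self.covariate_names)}, "
            f"prevalence={self.prevalence:.3f})"
        )
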