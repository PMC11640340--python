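"""CSV interchange for cohorts and evidence tables.

Dialect: UTF-8, comma-separated, header required, '.' decimal, missing
values as empty cells.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import MODEL_COVARIATES, OUTCOME_COLUMN, Cohort

__all__ = ["load_cohort", "write_cohort", "write_evidence"]


def load_cohort(path, covariates=MODEL_COVARIATES, outcome=OUTCOME_COLUMN) -> Cohort:
    """Read a cohort CSV and validate its schema.

    Requires every covariate column and a binary outcome column; raises
    naming the missing column otherwise.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*covariates, outcome) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing required columns: {missing}")
    return Cohort(df, covariates=covariates, outcome=outcome)


def write_cohort(cohort: Cohort, path) -> Path:
    path = Path(path)
    cols = [c for c in cohort.data.columns]
    if "subject_id" not in cols:
        out = cohort.data.copy()
        out.insert(0, "subject_id", range(1, cohort.n + 1))
    else:
        out = cohort.data
    out.to_csv(path, index=False)
    return path


def write_evidence(evidence: pd.DataFrame, path) -> Path:
    path = Path(path)
    required = {"predictor", "q025_logodds", "q500_logodds", "q975_logodds"}
    if not required.issubset(evidence.columns):
        raise ValueError(f"evidence table must have columns {sorted(required)}")
    evidence.to_csv(path, index=False)
    return path
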