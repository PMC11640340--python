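"""Bayesian logistic regression estimator for margin-status prediction.

:class:`BayesianLogisticMargin` is a scikit-learn style classifier: it is
configured with a prior regime, fitted by MCMC, and predicts per-subject
average posterior-predictive probabilities of an R1 (positive-margin)
resection.  Module-level helpers (:func:`fit_bayes_logistic`,
:func:`check_convergence`) are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort
from .priors import INTERCEPT_TERM, PriorSpec, weakly_informative_prior
from .sampler import LogisticPosterior, PosteriorDraws, sample_posterior

__all__ = [
    "BayesianLogisticMargin",
    "Diagnostics",
    "fit_bayes_logistic",
    "check_convergence",
]


@dataclass
class Diagnostics:
    """Convergence diagnostics per coefficient."""

    rhat: dict[str, float]
    ess: dict[str, float]
    accept_rate: float
    rhat_threshold: float
    passed: bool

    def worst_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")


def check_convergence(draws: PosteriorDraws, rhat_threshold: float = 1.01) -> Diagnostics:
    """Split-R-hat and bulk ESS per coefficient via ArviZ.

    A fit passes when every coefficient's R-hat is below the threshold.
    With a single chain the split diagnostic is still computed but a
    warning flags its reduced sensitivity.
    """
    if draws.n_chains < 2:
        warnings.warn(
            "convergence diagnostics from a single chain are unreliable; "
            "use >= 2 chains",
            stacklevel=2,
        )
    azd = az.from_dict(
        posterior={t: draws.draws[:, :, i] for i, t in enumerate(draws.term_names)}
    )
    rhat_ds = az.rhat(azd)
    ess_ds = az.ess(azd)
    rhat = {t: float(rhat_ds[t].values) for t in draws.term_names}
    ess = {t: float(ess_ds[t].values) for t in draws.term_names}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    passed = bool(finite) and all(v < rhat_threshold for v in finite)
    return Diagnostics(
        rhat=rhat,
        ess=ess,
        accept_rate=getattr(draws, "accept_rate", float("nan")),
        rhat_threshold=rhat_threshold,
        passed=passed,
    )


class BayesianLogisticMargin(ClassifierMixin, BaseEstimator):
    """Bayesian logistic regression with normal priors, fitted by MCMC.

    Parameters
    ----------
    priors : PriorSpec or "weak"
        Prior regime.  ``"weak"`` builds the weakly informative
        ``normal(0, 2.5/s_x)`` priors from the training data.
    chains, iterations, warmup, thin : int
        MCMC settings: ``chains`` adaptive Metropolis chains, each keeping
        ``iterations`` draws after ``warmup`` adaptation steps, one draw
        per ``thin`` Metropolis steps.
    seed : int
        Seed for all sampling randomness.
    center : bool
        Mean-center covariates before sampling (coefficients are mapped
        back to the original scale, so the estimand is unchanged).
    intercept_scale : float
        Scale of the vague normal prior on the intercept.
    rhat_threshold : float
        Split-R-hat pass threshold for the convergence flag.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Posterior samples on the original covariate scale
        (chains x iterations x terms; intercept first).
    diagnostics_ : Diagnostics
        R-hat / ESS per coefficient.
    term_names_ : list of str
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        priors: PriorSpec | str = "weak",
        chains: int = 4,
        iterations: int = 1000,
        warmup: int = 1000,
        thin: int = 10,
        seed: int = 0,
        center: bool = True,
        intercept_scale: float = 10.0,
        rhat_threshold: float = 1.01,
    ):
        self.priors = priors
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.thin = thin
        self.seed = seed
        self.center = center
        self.intercept_scale = intercept_scale
        self.rhat_threshold = rhat_threshold

    # ------------------------------------------------------------------
    def _validate_Xy(self, X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D (subjects x covariates)")
            names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values; "
                             "restrict to complete cases first")
        if y.size and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        return X, y, names

    def _resolve_priors(self, X: np.ndarray, names: list[str]) -> PriorSpec:
        if isinstance(self.priors, PriorSpec):
            missing = [t for t in (INTERCEPT_TERM, *names) if t not in self.priors.priors]
            if missing:
                raise ValueError(f"PriorSpec is missing terms: {missing}")
            return self.priors
        if self.priors != "weak":
            raise ValueError("priors must be a PriorSpec or 'weak'")
        if X.shape[0] < 2:
            raise ValueError(
                "weakly informative priors need >= 2 subjects to estimate "
                "covariate SDs; pass an explicit PriorSpec instead"
            )
        cohort = Cohort(
            pd.DataFrame(X, columns=names).assign(r1=0).iloc[:, :],
            covariates=names,
        )
        # outcome column irrelevant to SD computation above; rebuild cleanly
        return weakly_informative_prior(cohort, intercept_scale=self.intercept_scale)

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "BayesianLogisticMargin":
        """Sample the posterior of the coefficients given (X, y).

        A zero-row ``X`` is allowed and yields the prior as posterior.
        """
        X, y, names = self._validate_Xy(X, y)
        if X.shape[0]:
            sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
            const = [names[j] for j in range(X.shape[1]) if X.shape[0] > 1 and sds[j] == 0]
            if const:
                raise ValueError(f"constant covariates cannot be fitted: {const}")
        prior_spec = self._resolve_priors(X, names)

        order = [INTERCEPT_TERM, *names]
        loc = prior_spec.locations(order)
        scale = prior_spec.scales(order)

        means = X.mean(axis=0) if (self.center and X.shape[0]) else np.zeros(X.shape[1])
        Xc = X - means
        design = np.column_stack([np.ones(X.shape[0]), Xc])

        post = LogisticPosterior(design, y, loc, scale)
        draws = sample_posterior(
            post,
            term_names=order,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            thin=self.thin,
            seed=self.seed,
        )
        if self.center and X.shape[0]:
            # intercept back to the original covariate scale
            arr = draws.draws.copy()
            arr[:, :, 0] -= arr[:, :, 1:] @ means
            draws = PosteriorDraws(
                arr, draws.term_names, draws.seed, draws.warmup, draws.thin,
                draws.accept_rate,
            )

        self.term_names_ = order
        self.feature_names_ = names
        self.prior_spec_ = prior_spec
        self.draws_ = draws
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        self.diagnostics_ = check_convergence(draws, self.rhat_threshold) \
            if self.chains >= 2 else None
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Average posterior-predictive probabilities, shape (n, 2)."""
        p1 = self.posterior_predictive(X)
        return np.column_stack([1.0 - p1, p1])

    def posterior_predictive(self, X) -> np.ndarray:
        """Per-subject mean over draws of ``logistic(intercept + x.beta)``."""
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns matching the fitted terms"
            )
        from scipy.special import expit

        theta = self.draws_.pooled()  # (draws, terms)
        eta = theta[:, 0][None, :] + X @ theta[:, 1:].T  # (n, draws)
        return expit(eta).mean(axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.posterior_predictive(X) >= 0.5).astype(float)


# ----------------------------------------------------------------------
def fit_bayes_logistic(
    cohort: Cohort,
    priors: PriorSpec | str = "weak",
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 1000,
    thin: int = 10,
    seed: int = 0,
) -> tuple[PosteriorDraws, BayesianLogisticMargin]:
    """Fit the margin model on a cohort (complete cases); returns draws + model."""
    cc = cohort.complete_cases()
    model = BayesianLogisticMargin(
        priors=priors, chains=chains, iterations=iterations, warmup=warmup,
        thin=thin, seed=seed,
    )
    Xdf = cc.data[list(cc.covariate_names)]
    model.fit(Xdf, cc.y)
    return model.draws_, model
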