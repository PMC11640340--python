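import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import marginbayes as mb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    return mb.default_covariate_specs()


@pytest.fixture(scope="session")
def truth(specs):
    return mb.default_true_model(specs=specs)


@pytest.fixture(scope="session")
def cohort205(specs, truth):
    return mb.generate_cohort(205, specs=specs, truth=truth, seed=7)


@pytest.fixture(scope="session")
def fitted_default(cohort205):
    """Default-settings fit on the reference synthetic cohort."""
    draws, model = mb.fit_bayes_logistic(cohort205, seed=1)
    return draws, model


@pytest.fixture()
def two_term_data():
    """Small intercept + one-covariate dataset for oracle comparisons."""
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 1.0, size=200)
    eta = -0.5 + 0.8 * x
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    return pd.DataFrame({"x": x}), y
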