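"""Posterior-predictive probabilities, AUC and δ-sweep selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import marginbayes as mb
from marginbayes.cohort import Cohort
from marginbayes.prediction import select_inflection
from marginbayes.priors import INTERCEPT_TERM
from marginbayes.sampler import PosteriorDraws


def _tiny_cohort(x_values, y_values):
    df = pd.DataFrame({"x": x_values, "r1": y_values})
    return Cohort(df, covariates=["x"])


def _draws(theta_rows, names=("intercept", "x")):
    arr = np.asarray(theta_rows, dtype=float)[None, :, :]
    return PosteriorDraws(arr, list(names), seed=0, warmup=0, thin=1, accept_rate=0.3)


def pair_counting_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle: all (positive, negative) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                concordant += 1
            elif p == q:
                concordant += 0.5
    return concordant / total


class TestPosteriorPredictive:
    def test_all_zero_draws_give_half(self):
        cohort = _tiny_cohort([0.0, 1.0, -2.0], [0, 1, 0])
        probs = mb.posterior_predictive_probs(_draws([[0.0, 0.0]] * 10), cohort)
        assert np.allclose(probs, 0.5)

    def test_single_draw_is_its_logistic_score(self):
        cohort = _tiny_cohort([2.0], [1])
        probs = mb.posterior_predictive_probs(_draws([[0.5, 1.0]]), cohort)
        expected = 1.0 / (1.0 + np.exp(-(0.5 + 1.0 * 2.0)))
        assert probs[0] == pytest.approx(expected, rel=1e-12)

    def test_saturated_draws_average_to_half(self):
        cohort = _tiny_cohort([1.0], [1])
        probs = mb.posterior_predictive_probs(_draws([[-20.0, 0.0], [20.0, 0.0]]), cohort)
        assert probs[0] == pytest.approx(0.5, abs=1e-8)

    def test_term_mismatch_rejected(self):
        cohort = _tiny_cohort([1.0], [1])
        with pytest.raises(ValueError, match="covariates"):
            mb.posterior_predictive_probs(
                _draws([[0.0, 0.0]], names=("intercept", "unknown")), cohort
            )

    def test_probabilities_in_unit_interval(self, fitted_default, cohort205):
        draws, model = fitted_default
        probs = mb.posterior_predictive_probs(draws, cohort205)
        assert probs.shape == (cohort205.n,)
        assert np.all((probs > 0) & (probs < 1))
        # estimator surface agrees with the functional surface
        alt = model.posterior_predictive(cohort205.data[list(cohort205.covariate_names)])
        assert np.allclose(probs, alt)


class TestAUC:
    def test_perfect_separation(self):
        assert mb.compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_tie_rule(self):
        assert mb.compute_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert mb.compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single outcome class"):
            mb.compute_auc([0.1, 0.2], [1, 1])

    @given(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9, 1.0]),
                 min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_equals_pair_counting_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert mb.compute_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=50)
        labels = rng.binomial(1, 0.4, size=50)
        base = mb.compute_auc(scores, labels)
        assert mb.compute_auc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert mb.compute_auc(10 + 0.01 * scores, labels) == pytest.approx(base)


class TestInflectionSelection:
    def test_flat_curve_falls_back_to_smallest_max(self):
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        delta, rule = select_inflection(grid, np.full(5, 0.7))
        assert delta == 0.1 and rule == "max-fallback"

    def test_concave_monotone_curve_falls_back_to_max(self):
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        aucs = np.array([0.60, 0.68, 0.72, 0.73, 0.733])
        # second differences (-0.04, -0.03, -0.007) never change sign
        delta, rule = select_inflection(grid, aucs)
        assert delta == 0.9 and rule == "max-fallback"

    def test_curvature_sign_change_selects_grid_point(self):
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        aucs = np.array([0.60, 0.62, 0.70, 0.72, 0.725])
        # second differences (+0.06, -0.06, -0.015): first change at delta 0.5
        delta, rule = select_inflection(grid, aucs)
        assert delta == 0.5 and rule == "inflection"

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="length >= 4"):
            select_inflection(np.array([0.1, 0.5, 0.9]), np.array([0.6, 0.7, 0.8]))
        with pytest.raises(ValueError, match="ascending"):
            select_inflection(
                np.array([0.1, 0.5, 0.4, 0.9]), np.array([0.6, 0.7, 0.8, 0.9])
            )


@pytest.fixture(scope="module")
def small_informative_setup():
    specs = mb.default_covariate_specs()
    truth = mb.default_true_model(specs=specs)
    cohort = mb.generate_cohort(150, specs=specs, truth=truth, seed=17)
    cc = cohort.complete_cases()
    weak = mb.weakly_informative_prior(cc)
    ev = mb.generate_literature_evidence(truth, ci_width_factor=0.8, seed=17)
    evidence = {
        row["predictor"]: mb.ElicitedQuantiles(
            row["q025_logodds"], row["q500_logodds"], row["q975_logodds"]
        )
        for _, row in ev.iterrows()
    }
    informative = mb.elicited_prior(evidence, cc.covariate_names, fallback=weak)
    return cc, weak, informative


FAST = dict(chains=2, iterations=250, warmup=400, thin=3)
# short chains give noisy split-R-hat; tests that assert convergence at the
# 1.01 default use full-length default settings instead
FAST_SWEEP = dict(**FAST, rhat_threshold=1.2)


class TestDeltaSweep:
    def test_sweep_mechanics_and_reproducibility(self, small_informative_setup):
        cc, _, informative = small_informative_setup
        grid = np.array([0.1, 0.35, 0.6, 0.85])
        res1 = mb.delta_sweep(cc, informative, grid, seed=5, **FAST_SWEEP)
        res2 = mb.delta_sweep(cc, informative, grid, seed=5, **FAST_SWEEP)
        assert np.array_equal(res1.auc_per_delta, res2.auc_per_delta)
        assert res1.selected_delta in grid
        assert res1.selection_rule in ("inflection", "max-fallback")
        assert np.all((res1.auc_per_delta > 0) & (res1.auc_per_delta < 1))
        frame = res1.to_frame()
        assert list(frame.columns) == ["delta", "auc", "converged"]

    def test_grid_outside_bounds_rejected(self, small_informative_setup):
        cc, _, informative = small_informative_setup
        with pytest.raises(ValueError, match=r"\[0.1, 0.95\]"):
            mb.delta_sweep(cc, informative, np.array([0.05, 0.3, 0.6, 0.9]), **FAST_SWEEP)

    def test_discounting_moves_toward_weak_fit(self, small_informative_setup):
        """Larger delta pulls posterior means from the informative fit
        toward the data-dominated (weak-prior) fit."""
        cc, weak, informative = small_informative_setup
        Xdf = cc.data[list(cc.covariate_names)]
        kw = dict(chains=2, iterations=400, warmup=500, thin=4)
        m_weak = mb.BayesianLogisticMargin(priors="weak", seed=9, **kw).fit(Xdf, cc.y)
        dist = {}
        for delta in (0.1, 0.9):
            spec = mb.apply_power_prior(informative, delta)
            m = mb.BayesianLogisticMargin(priors=spec, seed=9, **kw).fit(Xdf, cc.y)
            gaps = [
                abs(m.draws_.term(t).mean() - m_weak.draws_.term(t).mean())
                for t in m.term_names_
                if t != INTERCEPT_TERM
            ]
            dist[delta] = np.mean(gaps)
        assert dist[0.9] <= dist[0.1] + 0.03


def test_informative_priors_do_not_hurt_when_correct():
    """Evidence-consistent priors keep out-of-sample AUC competitive at
    small n (in-sample AUC would reward the weak prior's overfitting)."""
    specs = mb.default_covariate_specs()
    truth = mb.default_true_model(specs=specs)
    test_cohort = mb.generate_cohort(1500, specs=specs, truth=truth, seed=999)
    Xtest = test_cohort.data[list(test_cohort.covariate_names)]
    auc_weak, auc_inf = [], []
    for seed in range(10):
        cohort = mb.generate_cohort(100, specs=specs, truth=truth, seed=100 + seed)
        cc = cohort.complete_cases()
        if cc.prevalence in (0.0, 1.0):
            continue
        Xdf = cc.data[list(cc.covariate_names)]
        weak_spec = mb.weakly_informative_prior(cc)
        ev = mb.generate_literature_evidence(truth, ci_width_factor=0.5, seed=seed)
        evidence = {
            r["predictor"]: mb.ElicitedQuantiles(
                r["q025_logodds"], r["q500_logodds"], r["q975_logodds"]
            )
            for _, r in ev.iterrows()
        }
        inf_spec = mb.elicited_prior(evidence, cc.covariate_names, fallback=weak_spec)
        for spec, sink in ((weak_spec, auc_weak), (inf_spec, auc_inf)):
            m = mb.BayesianLogisticMargin(priors=spec, seed=seed, **FAST).fit(Xdf, cc.y)
            sink.append(mb.compute_auc(m.posterior_predictive(Xtest), test_cohort.y))
    assert np.mean(auc_inf) >= np.mean(auc_weak) - 0.01
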