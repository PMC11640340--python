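# marginbayes

Bayesian prediction of microscopic margin status (R1) after neoadjuvant
therapy in pancreatic ductal adenocarcinoma.

Achieving a clear surgical margin (R0) is the main goal of pancreatic
resection after neoadjuvant therapy (NAT), but preoperative imaging is a
poor guide to which explorations will end with tumor within 1 mm of a
margin (R1). `marginbayes` implements a Bayesian logistic regression for
the per-patient R1 risk from eight preoperative predictors — age, ASA
physical status 3–4, arterial involvement, post-NAT tumor diameter,
venous contact, pancreatic-body location, preoperative radiotherapy and
normal CA19-9 — with three prior regimes and a principled way to weigh
historical evidence against the data at hand. It is aimed at
biostatisticians and surgical-oncology researchers building or stress
testing margin-risk models.

## The model

For subject $i$ with covariates $x_i$ and outcome $y_i \in \{0,1\}$
(1 = R1):

$$y_i \sim \mathrm{Bernoulli}\big(\mathrm{logit}^{-1}(\alpha + x_i^\top \beta)\big)$$

with independent normal priors on the log-odds coefficients:

* **Weakly informative**: $\beta_j \sim \mathcal N(0,\, 2.5/s_{x_j})$,
  where $s_{x_j}$ is the predictor's sample SD — vague in any units.
* **Informative**: for each predictor, a normal is fitted by least
  squares on the CDF to literature-elicited quantiles
  $(q_{0.025}, q_{0.5}, q_{0.975})$ of the log-odds effect (SHELF-style
  elicitation from published ORs with 95% CIs).
* **Power prior**: the informative prior's *variance* is inflated by
  $(1+\delta)$, $\delta \in [0.1, 0.95]$, discounting the historical
  evidence; $\delta = 0.5$ adds 50% prior variance.

Posteriors are sampled with adaptive random-walk Metropolis chains
preconditioned by a Laplace approximation (4 chains × 1000 retained
draws by default, split-R-hat/ESS diagnostics via ArviZ). Coefficients
are reported as odds ratios with 95% credible intervals and the
probability of direction $p_d \in [0.5, 1]$ — the posterior mass sharing
the sign of the posterior median. Predictive performance is the AUC of
the per-subject average posterior-predictive R1 probability, and the
discounting factor is selected at the inflection point of the AUC-vs-δ
curve (second-finite-difference sign change; AUC maximum as fallback).

Because the motivating cohort (~205 patients, R1 prevalence 26.8%) is
not public, the package ships a seeded synthetic-cohort generator
calibrated to the published covariate marginals and odds ratios, so the
whole pipeline is testable end to end.

## Worked example

```python
import marginbayes as mb

cohort = mb.generate_cohort(205, seed=7)          # synthetic, prevalence ~0.27
draws, model = mb.fit_bayes_logistic(cohort, seed=1)  # weak priors
table = mb.summary_table(mb.summarize_coefficients(draws))
probs = mb.posterior_predictive_probs(draws, cohort)
print(table.round(3).to_string(index=False))
print(f"in-sample predictive AUC: {mb.compute_auc(probs, cohort.y):.3f}")
```

prints

```
                term    or  ci_low  ci_high  pd_percent
           intercept 0.002   0.000    0.052     100.000
           age_years 1.018   0.982    1.055      83.600
              asa_34 1.612   0.756    3.451      88.875
arterial_involvement 3.919   1.870    8.515      99.950
    post_nat_size_mm 1.114   1.055    1.184     100.000
      venous_contact 1.415   0.680    2.968      82.650
       body_location 4.898   2.044   12.224      99.975
  preop_radiotherapy 0.925   0.366    2.242      56.825
        ca199_normal 0.658   0.306    1.364      88.075
in-sample predictive AUC: 0.767
```

Each row is a predictor's multiplicative effect on the odds of an R1
resection: e.g. arterial involvement multiplies the odds by ~3.9 (95%
CrI 1.9–8.5) in this simulated cohort, with $p_d$ essentially 100% —
the posterior is almost entirely on the harmful side. `pd_percent` near
50 (radiotherapy) means the data carry no directional information. The
AUC of 0.767 is the in-sample concordance of the averaged
posterior-predictive probabilities.

The same pipeline is scriptable from the shell:

```bash
margin-bayes synth --n 205 --seed 7 --prevalence 0.268 \
    --out cohort.csv --evidence evidence.csv
margin-bayes fit --cohort cohort.csv
margin-bayes sweep --cohort cohort.csv --evidence evidence.csv \
    --grid 0.1:0.95:0.05
margin-bayes run --config run.yaml   # full multi-scenario report
```

A `run.yaml` needs a seed plus either file inputs or a `synthetic:`
block; see `marginbayes.pipeline.PipelineConfig` for every field.

## Scikit-learn interface

`mb.BayesianLogisticMargin` is a standard estimator: `fit(X, y)`,
`predict_proba`, `get_params`/`set_params`, fitted attributes `draws_`
and `diagnostics_`. It composes with sklearn model selection; the
module-level functions are thin wrappers over it.
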