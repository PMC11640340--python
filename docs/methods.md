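# Methods

## Model and estimand

The outcome is the binary microscopic margin status of a pancreatic
resection after neoadjuvant therapy (R1 = invasive carcinoma within
1 mm of any margin). For subject $i$,

$$y_i \sim \mathrm{Bernoulli}(\pi_i), \qquad
  \mathrm{logit}(\pi_i) = \alpha + x_i^\top \beta,$$

with eight preoperative covariates: age (years), ASA 3–4, arterial
involvement, post-NAT tumor diameter (mm), venous contact, tumor in the
pancreatic body, preoperative radiotherapy, and normal preoperative
CA19-9. All priors are independent normals on the log-odds scale; the
analysis is complete-case (rows with any missing model covariate are
dropped before fitting).

## Prior regimes

**Weakly informative.** $\beta_j \sim \mathcal N(0, 2.5/s_{x_j})$ with
$s_{x_j}$ the sample SD (ddof = 1) of covariate $j$. The product
$\sigma_{prior} \cdot s_x = 2.5$ is invariant to the covariate's units,
so the prior is equally vague however a predictor is measured. A
constant covariate is a hard error. The intercept prior is
$\mathcal N(0, 10)$ — wide enough to be irrelevant at any realistic
prevalence — and is configurable (`intercept_scale`).

**Elicited.** Literature evidence per predictor arrives as the 0.025,
0.5 and 0.975 quantiles of the log-odds effect (equivalently an OR with
95% CI, log-transformed). A normal $(\mu, \sigma)$ is fitted by least
squares between its CDF at the three quantiles and (0.025, 0.5, 0.975).
The optimizer is Nelder–Mead on $(\mu, \log\sigma)$ from the
moment-based start $\mu_0 = q_{0.5}$, $\sigma_0 = (q_{0.975} -
q_{0.025})/3.92$; for exactly-normal inputs the start already solves the
problem and the fit is a refinement, so recovery is at optimizer
tolerance (~1e-8). Only the normal family is supported. Asymmetric
intervals are resolved by the least-squares criterion rather than by
either closed form.

**Power prior.** Discounting by $\delta \in [0, 1]$ multiplies each
coefficient's prior *variance* by $(1+\delta)$. The variance reading is
adopted because the worked semantics of the method are stated in
variance terms ($\delta = 0.5$ ⇒ +50% variance); a literal
scale-multiplication variant is available via `discount_on="scale"`.
The elicited location is retained by default — discarding it would
discard the very evidence being discounted — and `zero_location=True`
recenters the discounted priors at zero for the strict zero-mean
convention some power-prior formulations print. The intercept
prior is not discounted (it encodes no historical evidence) unless
`discount_intercept=True`.

## Sampling

The posterior $\propto$ Bernoulli-logistic likelihood × normal priors
is log-concave, which makes a Laplace-preconditioned random-walk
Metropolis sampler efficient and fully self-contained:

1. Find the mode by L-BFGS with analytic gradient; take the proposal
   covariance as the inverse negative Hessian there, scaled by
   $2.38^2/d$.
2. Run 4 chains from overdispersed starts (mode + 2 Laplace SDs), each
   with 1000 adaptation steps (Robbins–Monro tuning of a global step
   factor toward 0.234 acceptance), then 1000 retained draws with
   internal thinning of 10 Metropolis steps per draw.

Thinning at 10 puts the bulk ESS near or above 1000 of 4000 pooled
draws and keeps split-R-hat below 1.01 across seeds on the default
cohort; one fit at n = 205 costs well under a second. Covariates are
mean-centered before sampling (better conditioning of the Hessian) and
the intercept draws are shifted back afterwards, so reported
coefficients are on the original scale and the estimand is unchanged.
With zero subjects the likelihood vanishes and the machinery samples the
prior exactly — used as a correctness check. Convergence is assessed
with ArviZ split-R-hat and bulk ESS per coefficient (threshold 1.01,
configurable); extreme separation shows up as divergent chains and a
failed R-hat gate rather than a silent wrong answer. The retained/warmup
split of "1000 iterations in four chains" is an explicit choice: 1000
adaptation plus 1000 retained per chain.

## Summaries

Odds ratios are $\exp(\mathrm{median}(\beta))$ — invariant under the
log transform — with `point="mean"` available; intervals are
equal-tailed empirical percentiles (type-7 linear interpolation, noted
because endpoints at 4000 draws wobble in the third decimal). The
probability of direction is the fraction of draws sharing the sign of
the posterior median; exact zeros count half, an exactly-zero median
reports 0.5, and the result is floored at 0.5 so sampling granularity
cannot dip below the theoretical bound.

## Prediction and δ selection

Per-subject risk is the average over all retained draws of
$\mathrm{logit}^{-1}(\alpha + x^\top\beta)$ — the mean of the posterior
predictive, not the plug-in at the posterior mean. Discrimination is
the Mann–Whitney AUC (ties counted 1/2), computed in-sample on the
fitting cohort by default; out-of-sample scoring is available by
passing a different cohort.

The discounting factor is swept over δ = 0.10 to 0.95 in steps of 0.05
(the wider of the two printed grid conventions). The "equilibrium" δ is
the grid point at the first sign change between consecutive
second-order finite differences of the AUC-vs-δ curve; with no sign
change (flat or uniformly curved curves) the AUC-maximizing δ is used,
smallest on ties, and the result is tagged `max-fallback`. Because
Monte-Carlo noise can fabricate curvature changes, each AUC uses all
4000 retained draws and an optional 3-point moving average (`smooth`,
off by default) can be applied before detection. Fits failing the R-hat
gate are excluded from selection with a warning.

## Synthetic cohort generator

The generator emulates the kind of NAT-resection cohort the model is
meant for: n = 205 subjects, R1 prevalence 26.8%, and the published
covariate marginals — age ≈ N(64, 10.4²) years truncated to [18, 100],
post-NAT size ≈ N(25, 7.4²) mm truncated to [1, 120] (medians/IQRs
mapped to mean/SD via SD = IQR/1.349 under approximate normality),
ASA 3–4 24%, body location 21%, radiotherapy 25%, normal CA19-9 56%.
Arterial and venous involvement are only published as a combined "any
vascular involvement" (57%); the defaults split this once as 30%
arterial / 45% venous, roughly reflecting that venous contact is the
more common finding in borderline-resectable disease. True effects
default to the published multivariable odds ratios (arterial 5.69, body
2.79, ASA 1.70, venous 1.62, size 1.08/mm, age 1.03/year, normal
CA19-9 0.86; radiotherapy has no published estimate and is null). The
intercept is solved by Brent root-finding on a 200,000-draw fixed-seed
Monte-Carlo estimate of the marginal prevalence (closed-form logit when
all effects are zero).

Covariates are simulated independently: no joint distribution is
published, and inventing correlations would claim information that does
not exist. Missingness is optional MCAR only (the source's per-variable
denominators imply missingness but no mechanism). Consequently, passing
tests show the pipeline recovers known effects and calibrated
prevalence under independent marginals — they do not certify behavior
under the correlated covariates (vascular involvement co-occurring with
larger tumors, etc.) or informative missingness of a real registry.

The synthetic literature-evidence generator centers each predictor's
elicited quantiles near the true log-odds with SD
$\text{ci\_width\_factor}\times(0.02 + 0.15\,|\beta|)$ — proportional
widths so per-unit effects of continuous covariates get realistically
narrow intervals — plus a seeded center jitter of 0.3 prior-SDs.

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning (per-chain, per-δ streams).
* Empty posterior sample → error; single chain → diagnostics computed
  with a warning; single-class outcome → AUC is a hard error.
* The δ grid must be ascending, within [0.1, 0.95], length ≥ 4.
* Prior variance inflation is exact arithmetic, tested to 1e-12.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances while the whole suite stays fast:
marginal calibration at n = 50,000 (4·SE), oracle-equivalence fits at
n = 200 against a 201×201 quadrature grid (3·MCSE), parameter recovery
at n = 2,000 over 20 seeds with shortened chains (bias < 0.1 log-odds,
interval coverage ≥ 90%), and sweep/pipeline integration runs at
n = 100–205 with either default chains (when convergence itself is
asserted) or short chains with a relaxed R-hat gate (when mechanics and
determinism are the point).

## Known limitations

* The sampler is random-walk Metropolis; for much higher-dimensional
  models a gradient-based sampler would mix better. The contract is
  enforced by quadrature-oracle equivalence, not by the backend.
* In-sample AUC is optimistic; the optional k-fold path is not the
  default because the reference procedure is in-sample.
* No imputation, no model comparison (WAIC/LOO), no survival endpoints,
  no non-normal elicitation families.
* A credible interval spanning 1 together with $p_d$ near 100% cannot
  occur under the implemented definitions; such combinations in
  external reports are not reproduced.
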