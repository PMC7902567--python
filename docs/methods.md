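# Methods

This note records the modelling choices, defaults and limitations of
`tripletaft` in one place. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is quoted
from elsewhere.

## The outcome model

Both endpoints are modelled with a lognormal accelerated failure time
(AFT) regression: `log T = x'β + σε`, `ε ~ N(0,1)`, with right-censored
records contributing `log Φ(−z)`. The AFT form is chosen because its
exponentiated coefficients are time ratios — directly interpretable as
multiplicative changes in median time-to-event — and because it does
not require proportional hazards, which routinely fails for
chemotherapy comparisons with converging long-term survival. No other
AFT error family (Weibull, log-logistic) is implemented; the lognormal
variant is the package's single, tested likelihood.

The design matrix couples a treatment indicator (DPF vs PF reference)
with ten registry confounders: ECOG performance status, Lauren
subtype, histological grade, ascites, stage, liver tumour burden
(five ordinal levels entered as dummies), number of involved organs,
platinum compound, log neutrophil/lymphocyte ratio, age and calendar
year. Continuous terms are centred and scaled by constants stored in
the design spec, so the sampler sees unit-scale columns while patient
profiles are transformed identically at prediction time. Reference
levels follow the clinical contrasts of interest (diffuse subtype,
ECOG 0, no liver involvement, oxaliplatin, metastatic stage).

### Splines

Age (and any other continuous covariate on request) enters through a
restricted cubic spline in Harrell's truncated-power parameterisation:
`k` knots give `k−1` columns (the linear term plus `k−2` cubic terms
scaled by `(t_k − t_1)²`), with the basis exactly linear beyond the
boundary knots and C² at the knots — both properties are verified by
finite differences in the tests. Knot placement is the standard
10th/50th/90th percentile convention for 3 knots (configurable); the
basis construction is hand-built because this exact parameterisation
is load-bearing for the linear-extrapolation behaviour of effect
curves beyond the observed covariate range.

## Priors

Three classes, all normal on the log time-ratio scale:

* **Treatment.** Elicited from an external pooled hazard ratio by
  `mean = −ln(HR)` and `sd = (ln hi − ln lo)/(2·1.96)`. For the OS
  default the elicitation gives mean 0.1508 and CI-derived sd 0.0503;
  the packaged default keeps the published rounding `N(0.15, 0.045)`
  (and `N(0.27, 0.07)` for PFS). The HR→TR sign convention treats a
  proportional-hazards benefit (HR < 1) as a positive log time ratio;
  this correspondence is exact only in special AFT families and is
  used here as an elicitation convention, not a theorem. The second
  prior argument is a standard deviation: a variance reading would
  make the "informative" OS prior four times wider than its source
  interval, which is not tenable.
* **Interactions.** Skeptical `N(0, 0.05)`: the prior probability of a
  subgroup deviation beyond ±15% is ≈0.005, so only consistent data
  move subgroup estimates far from the overall effect.
* **Nuisance.** `N(0, 2.5)` on unit-scaled covariates, `N(ln 10, 10)`
  on the intercept (months scale), `N(0, 2)` on `log σ`. Three modes
  are exposed: `informative` (above), `weak` (treatment `N(0,1)`,
  skeptical interactions), and `flat` (`N(0, 100)` on treatment *and*
  interactions) whose posterior medians reproduce maximum-likelihood
  fits and anchor the oracle tests.

## Sampling and diagnostics

The posterior is sampled by a Metropolis–Hastings kernel mixing, with
equal probability per iteration:

* an adaptive random-walk step — proposal covariance re-estimated from
  the warmup history, global scale tuned by Robbins–Monro toward 28%
  acceptance; and
* an independence step proposing from a multivariate t (8 df,
  covariance inflated 20%) centred at the penalised mode, which is
  found by BFGS with analytic gradients and whose curvature is an
  exact finite-difference Hessian of that gradient.

The independence component makes draws nearly independent when the
posterior is close to its Laplace approximation (the usual case for
these log-concave likelihoods at registry sample sizes); the
random-walk component keeps the kernel valid and mobile when it is
not. Chains start from independent jitters of the mode; all
randomness flows from a single seed, so fits are exactly reproducible.
Defaults: 4 chains, 1000 warmup, 1000 retained draws each. The kernel
is frozen after warmup.

Convergence is monitored by split-chain potential scale reduction
(R̂) and an FFT-autocorrelation effective sample size with Geyer
truncation; a fit is flagged (never silently discarded) when any
parameter reaches R̂ ≥ 1.1. The implementation is cross-checked
against an independent diagnostics library in the tests.

Correctness of the sampler is pinned distributionally rather than by
construction: an intercept-only, known-scale model must match the
normal–normal conjugate posterior in mean and sd; flat-prior posterior
medians must match an independent lognormal-AFT maximum-likelihood
fit within 1% relative or 0.005 absolute on every coefficient of a
500-patient cohort.

## Missing data

Columns whose missing fraction strictly exceeds 25% are dropped (the
boundary case, exactly 25%, is retained). The rest are multiply
imputed by fully conditional specification: numeric columns by
ordinary least squares plus normal residual noise, categorical columns
by multinomial logistic regression sampling from fitted class
probabilities, iterated 10 sweeps from random starting fills,
independently per imputed dataset (20 by default). Survival outcomes
enter the conditionals as log event time plus the event flag, the
standard recommendation when imputed covariates feed a survival model.
Posteriors fitted per completed dataset are pooled by concatenating
draws — a mixture of posteriors, appropriate because full posteriors
rather than point estimates are combined; moment-based pooling rules
are deliberately not used. Convergence is assessed per dataset before
pooling, since between-imputation spread is genuine uncertainty.
Not implemented: predictive mean matching, multilevel imputation,
MNAR sensitivity analyses; the imputation model draws no fresh
coefficient uncertainty (noise-only stochastic regression), which
mildly understates between-imputation variance at these missingness
rates.

## Estimands

Effects are summarised from posterior draws as: the posterior median
of `exp(β)` (median, not mean — invariant under the exponential), an
equal-tailed 95% credible interval, exceedance probabilities
`P(TR > 1.15)` and `P(TR > 1.30)`, and the mass of the region of
practical equivalence. The ROPE "no effect ± 10%" is read on the
coefficient scale, `|β| ≤ ln 1.10` (TR in [0.909, 1.10]); a
symmetric-on-TR band [0.90, 1.10] is available via `rope_scale="tr"`.
Conditional (subgroup) effects add the interaction draws evaluated at
a patient profile to the treatment main effect, per draw. The
calculator defines the triplet prediction as the doublet prediction
times the conditional time-ratio draw, which makes the per-draw ratio
of predicted medians identical to the conditional effect by
construction instead of only up to floating-point rounding.

## The synthetic registry

Because the source registry's patient-level data are not public, the
generator is the package's data source, and its defaults *are* the
study conditions:

* n = 1376; covariate marginals follow the published baseline table
  (ECOG 0/1/≥2 at 20/65/15%, diffuse/intestinal 59/41% among observed
  histology, ascites 25%, oxaliplatin 65%, age truncated-normal on
  [20, 89] with median ≈65, treatment years 2008–2019);
* treatment assignment is confounded by indication: a logistic
  propensity declining in age (with a quadratic taper) and in poor
  performance status, its intercept calibrated at n = 60,000 to the
  published 238/1376 triplet share;
* outcomes: PFS is exactly lognormal given covariates; OS is PFS plus
  an independent lognormal post-progression survival, which enforces
  `pfs ≤ os` row by row. Both components share the prognostic
  coefficient vector; treatment truth anchors at the published fits
  (PFS log-TR ln 1.23 at the diffuse reference with interaction
  ln(1.27/1.17); the post-progression treatment coefficient ln 1.09 is
  chosen so the implied overall OS time ratio is ≈1.19). Because OS
  is a convolution, it is not exactly lognormal; ground-truth recovery
  tests therefore target PFS, where the truth is exact, and the OS
  fits are interpreted as the working approximation they also are on
  real data. Intercepts are calibrated to the published whole-sample
  medians (OS 10.2, PFS 5.8 months);
* censoring: uniform accrual within the treatment year, an
  administrative cutoff shortly after the last accrual year, and rare
  exponential dropout, yielding ~85–90% observed events;
* missingness: Lauren 21%, grade 24%, missing-at-random on age and
  year (younger, earlier records lose histology more often), with the
  MAR intercept solved numerically so the marginal rate is exact;
  MCAR is available by configuration. Grade's 24% deliberately sits
  near the 25% screen threshold, exercising the screen's boundary.

What the generator does **not** emulate: HER2-positive disease and
trastuzumab-era treatment drift, second-line sequencing, toxicity as a
generative outcome (adverse events are handled only descriptively),
non-random site effects, and measurement error in covariates. Passing
tests therefore demonstrate that the pipeline recovers known truths
under a faithful-but-idealised registry, not that the published
registry estimates are themselves correct.

## Descriptive components

Relative dose intensity is `100 · delivered / planned` (mg/m² per
week, unit-free). Adverse-event relative risks are doublet-referenced
with Katz log-normal confidence intervals and a flagged 0.5 continuity
correction for zero cells; the Katz standard error matches a bootstrap
sd of log RR to ~2% in the asymptotic regime, but sits ~9% below it at
small counts (10 events per 100), where the bootstrap distribution is
discrete and skewed — a known limitation of the delta method, visible
in the tests. Age–probability curves for binary characteristics come
from logistic regression (IRLS to deviance change < 1e-8) on the
3-knot spline basis of age, with divergence of the coefficients
reported as probable complete separation.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest problem sizes chosen
for tight feedback loops: oracle equivalence on a 500-patient cohort
with 4×6000 retained draws; conjugate checks at n = 25; recovery and
shrinkage over 50 seeded cohorts of n = 1000 with 2×1500 retained
draws each; ground-truth recovery on one uncensored n = 20,000 cohort.
Coverage is asserted within its exact binomial 99% band (≥43/50) and
oracle agreement at 1% relative / 0.005 absolute per coefficient. Ties
and degenerate inputs fail loudly: non-distinct spline knots,
single-class logistic outcomes, all-missing columns, non-positive
times or scales, and single-chain diagnostics are all errors, not
warnings.
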