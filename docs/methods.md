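# Methods

`cohortsens` implements the battery of sensitivity analyses that
epidemiologists bring to a single observational exposure–outcome question:
is an association between a binary exposure and a binary outcome causally
interpretable once confounder mis-specification, residual confounding and
selection from missing data are taken seriously? The package couples each
analysis to a synthetic cohort generator with fully known causal structure,
so every method can be validated against ground truth rather than folklore.

## The estimation core

The base analysis is a complete-case logistic regression of the outcome on
the exposure, `logit P(Y=1) = α + β X + γᵀZ`, with Wald intervals and
p-values on the log-odds scale (profile-likelihood intervals would differ
only in extreme-count settings; Wald matches conventional epidemiological
reporting). Categorical covariates are expanded to indicator contrasts
against the most frequent level unless a reference is configured.

Three nested adjustment sets are fitted from the table's role map:
unadjusted; *confounders only* (role `confounder`); *confounders and/or
mediators* (adding role `confounder_or_mediator`). When a covariate may be
both a confounder and a mediator — the two-timepoint marital-status motif
in the generator — no single regression is unbiased: adjusting removes part
of the causal effect, not adjusting leaves a back-door path open. The two
adjusted fits therefore bracket the plausible range of the total effect,
and `run_scenarios` reports that interval and whether the two estimates
agree in sign.

Probability-scale effects use marginal standardization (g-computation):
the mean predicted probability with the exposure forced to 1 minus forced
to 0, over the complete-case rows, ×100 percentage points. Uncertainty
comes from a seeded nonparametric bootstrap of rows (default 500
resamples, percentile interval). Between-cohort coefficient comparisons
use the two-independent-samples z statistic
`(β₁−β₂)/√(se₁²+se₂²)`; where the two samples are couples rather than
independent draws this understates the covariance and the p-value is
anti-conservative — flagged here, not modelled.

## E-values

For a risk ratio RR ≥ 1 the E-value is `E = RR + sqrt(RR·(RR−1))`: the
minimum strength of association (risk-ratio scale) an unmeasured
confounder must have with both exposure and outcome to fully account for
the observed association. It inverts the bias-factor bound
`B(RR_EU, RR_UD) = RR_EU·RR_UD/(RR_EU+RR_UD−1)` along its diagonal (`RR =
E²/(2E−1)`); the package exposes both directions and the test suite
asserts the round trip to 1e-9. Odds ratios from logistic fits are first
mapped to approximate risk ratios; with a common outcome (prevalence
around 30% in the motivating setting) the square-root transformation
`RR ≈ √OR` is the default, with the identity used for rare outcomes.
Variants cover shifting an estimate to a non-null target (apply the
formula to the ratio of transformed estimates) and moving the confidence
limit nearer the null to the null (returns 1 when the interval already
spans it). Estimates below 1 are inverted first, so E-values are always
≥ 1 and symmetric under inversion.

## Generalised sensitivity analysis

The E-value works from summary statistics; the generalised sensitivity
analysis works from the individual-level data and the actual analysis
model. Its internals are defined here as follows (the published
description of the approach leaves them open):

- **Scale.** Partial associations are Pearson correlations of residuals.
  A covariate or pseudo-confounder U is residualized on the conditioning
  set by least squares; the binary exposure and outcome are residualized
  through their logistic fits (response residual `value − fitted p`,
  exactly mean-zero with an intercept). `r_x` conditions on the adjustment
  set; `r_y` conditions on the adjustment set plus the exposure.
- **Pseudo-confounder.** U = a·(exposure residual, standardized) +
  b·(outcome residual, standardized) + standard-normal noise. Because U is
  linear in fixed vectors, both achieved partial correlations are
  closed-form functions of (a, b) through two Gram matrices, so the damped
  fixed-point calibration (step-halving on oscillation, tolerance 0.005,
  at most 200 iterations) costs scalar arithmetic per step. A binary U
  thresholds the score at its median inside the iteration; achieved
  correlations are always re-measured on the final variable, so infeasible
  targets (e.g. r = 0.9 for a binary U, or jointly infeasible pairs near
  r_x²+r_y² ≈ 1) surface as a flagged non-convergence, never an exception.
- **Frontier.** For each grid value of r_x, bisection on r_y (resolution
  0.005, range [0, 0.9]) finds where the exposure z-statistic — averaged
  over `k_draws` calibrated U draws (default 50) sharing common random
  numbers across bisection candidates — crosses the target: 0 to nullify
  the point estimate, the critical value to remove significance. Refits
  including U use a Newton solver with a vanishing ridge (1e-6) so that
  probes with an extremely outcome-informative U cannot separate. The
  frontier is monotonized post hoc (r_y non-increasing in r_x). A baseline
  estimate already within ~2 SE of the null has nothing to nullify and
  returns the degenerate frontier {(0,0)} with a notice.
- **Benchmarking.** Each observed covariate (per indicator column) is
  benchmarked by leave-one-out partialling: its r_x and r_y given the
  remaining covariates. A planted ground-truth confounder generated by the
  synthetic module and deliberately excluded from the adjustment set is
  recovered by the frontier to within 0.05 in r_y at its benchmarked r_x
  (n = 20,000) — the package's strongest end-to-end validation of this
  module. A small upward offset (~0.02–0.04) is expected: a noisy linear
  pseudo-confounder with the same two partial correlations removes
  slightly less bias in a logistic model than the structural confounder
  itself, an effect of non-collapsibility.

## Multiple imputation

Missing data are handled by fully conditional specification: binary
variables by logistic posterior-predictive draws, continuous variables by
predictive mean matching (type-1 matching, donor pool of 5 nearest
predicted means, residual variance drawn from its scaled inverse-χ²),
categorical variables by multinomial-logit draws. Parameter uncertainty
uses the normal approximation at the MLE. Imputation models carry a ridge
of 1e-5 (analysis models never do); near-separated steps are damped and a
still-singular model raises an error naming the variable and iteration.
Missing cells are initialised from observed margins; variables are
revisited in ascending order of missingness count for a burn-in of 10
iterations (per-iteration chain means of the imputed cells are retained as
a convergence diagnostic); 50 imputations by default. Auxiliary variables
(role `auxiliary`) enter every imputation model through the predictor
matrix but are excluded from analysis models by their role — the mechanism
that makes Missing-At-Random plausible when missingness is driven by
exposure-caused variables such as smoking, alcohol use or depression.
Missingness indicators are *excluded* from imputation models by default:
they are typically collinear and can flip imputations into implausible
territory; a config flag re-enables them for comparison.

Analysis estimates are pooled by Rubin's rules: `q̄`, within-variance `w`,
between-variance `b`, total `t = w + (1+1/m)·b`, with Barnard–Rubin
small-sample degrees of freedom when the complete-data size is supplied,
and t-based intervals. The engine is cross-checked in the test suite
against statsmodels' independent MICE implementation on an MCAR cohort.

## Not-At-Random (delta-adjusted) imputation

When the exposure or outcome may cause its own missingness, a conditional
sensitivity parameter δ (log-odds) is added to the fitted linear predictor
of that variable's imputation model at every draw — the offset
formulation: those with missing data are `expit(η+δ)` rather than
`expit(η)` likely to be positive, conditional on everything else in the
model. With δ = 0 the code path is bit-for-bit standard MI (the anchor
invariant). A grid of deltas (default 0 to −2 by −0.25) is swept over the
exposure, the outcome, or their cartesian product; each cell is imputed,
analysed, pooled, and converted to a marginal sensitivity parameter (the
unadjusted log-odds difference in the variable between originally-missing
and observed records, with a flagged 0.5 continuity correction on empty
cells) plus the prevalence among the missing. Tipping-point detection
scans the axis or diagonal for the smallest |δ| at which the qualitative
conclusion (CI crossing the null, or the point estimate crossing a value)
flips relative to the (0,0) anchor.

**What delta adjustment does and does not correct.** If a variable's
missingness is logistic in its own value with coefficient δ given the
other modelled variables, then the conditional log-odds difference between
missing and observed records equals δ exactly, and the δ-adjusted
imputation model is correctly specified. The package's simulations show
that this correctly restores the *prevalence* of the variable among the
missing (and hence the MSP), but leaves the covariate-conditional odds
ratio almost unchanged: selection that factorizes into an
exposure-dependent part times an outcome-dependent part — which is exactly
what separate self-dependence mechanisms produce — cannot bias a
conditional odds ratio, so the MAR anchor is already approximately
unbiased for that estimand and matched deltas mainly move margins. Odds
ratios are in this sense remarkably selection-robust; tipping grids on the
OR scale speak to the stability of the association, not to a bias that
needed correcting. By contrast, selection that couples exposure- and
outcome-sides non-multiplicatively (e.g. exposure missingness depending
jointly on an exposure-caused auxiliary and on the outcome) does bias the
complete-case odds ratio; that structure is Missing At Random given the
observed data, and standard MI with auxiliaries removes the bias — the
scenario packaged as `synthdata.selection_bias_spec`.

## The synthetic cohort generator

All binary variables are logit-link Bernoulli so the log-odds-ratio
estimand is coherent everywhere. The default cohort emulates the
motivating study's scales: n = 13,000; exposure (regular attendance at a
place of worship) prevalence ≈ 0.14; outcome (ever donated blood)
prevalence ≈ 0.30; confounders age (standardized normal), education
(three levels 0.3/0.5/0.2) and employment (Bernoulli 0.7); a
marital-status pair measured at two timepoints acting as confounder
(time 1, typically unobserved) and mediator (time 3); a standard-normal
unmeasured confounder U (binary optional) entering both exposure and
outcome models; and exposure-caused binary auxiliaries (smoking, alcohol,
depression) that drive missingness. Missingness models are logistic in
observed covariates/auxiliaries with optional self-dependence deltas;
the mother-like preset yields ≈ 12% missingness in exposure and outcome,
the partner-like preset ≈ 40%. Intercepts were calibrated once at
n = 400,000 against these marginal targets and frozen. Generation order is
causal (confounders → U → time-1 mediator → exposure → time-3 mediator and
auxiliaries → outcome → missingness), one substream per stage from a
single master seed, so identical (spec, seed) pairs reproduce tables
byte-for-byte and adding a stage never perturbs earlier draws.

What the generator does *not* emulate: real covariate distributions beyond
order-of-magnitude prevalences, longitudinal repeated measures beyond the
two-timepoint motif, measurement error, and couple-level correlation
between the mother- and partner-like presets. Passing tests therefore
demonstrate correctness of the machinery under the declared causal
structure, not performance on any real cohort.

## Problem sizes and numerical choices

Test and validation runs use deliberately scaled problem sizes chosen as a
balance between Monte-Carlo error and turnaround: large-n recovery checks
at n = 50,000–100,000; CI-coverage at 500 replicates of n = 2,000;
GSA planted-confounder recovery at n = 20,000 over three seeds with 50
draws per grid point; MCAR imputation consistency at n = 5,000 with m = 20;
the recoverable-selection scenario at n = 30,000 with m = 15, burn-in 6;
delta-grid checks at n = 2,000–10,000 with m = 4–10. Logistic fits clip
linear predictors at ±30; Newton steps are norm-capped at 10; QR
factorizations drop numerically rank-deficient columns; bisections and
calibrations resolve to 0.005. Degenerate inputs (complete tables,
all-−∞ missingness intercepts, constant covariates, empty MSP cells) are
handled explicitly and tested.

## Known limitations

- The GSA calibration targets partial correlations of a *linear* pseudo-
  confounder; its frontier carries the small systematic offset described
  above and is not claimed to equal any particular proprietary
  implementation numerically.
- The mother/partner comparison assumes independent samples.
- Delta-adjusted tipping on the odds-ratio scale is conservative for
  purely self-dependent selection (see above); users interested in
  absolute-risk estimands should inspect the reported prevalences and
  MSPs, which do respond to the deltas.
- Multinomial imputation models are unpenalised; with sparse categories
  they may fail (the error names the variable and iteration) rather than
  silently shrink.
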