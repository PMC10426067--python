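# cohortsens

Sensitivity analyses for causal inference from observational cohort data.

Observational exposure–outcome studies rest on unverifiable assumptions:
that the right confounders were adjusted for, that no unmeasured
confounding remains, and that missing data did not select the analytic
sample in a biased way. `cohortsens` packages the standard battery of
quantitative bias analyses that interrogate those assumptions for a binary
exposure and binary outcome — the setting of, e.g., asking whether regular
religious attendance increases the probability of ever donating blood in a
birth-cohort study — together with a synthetic cohort generator with fully
known causal structure, so every method is validated against ground truth.

The battery:

- **Adjustment-scenario bracketing** — complete-case logistic fits under
  nested covariate sets (unadjusted; confounders only; confounders and/or
  mediators). When a covariate may be both confounder and mediator, the two
  adjusted fits bracket the plausible causal effect.
- **E-values** — the minimum risk-ratio strength `E = RR + √(RR(RR−1))` an
  unmeasured confounder needs with both exposure and outcome to explain an
  association away (or shift it to a target, or erase its significance),
  with the common-outcome `RR ≈ √OR` transformation.
- **Generalised sensitivity analysis** — repeatedly simulates a
  pseudo-confounder calibrated to target partial correlations `(r_x, r_y)`
  with exposure and outcome, traces the frontier of pairs that nullify the
  estimate, and benchmarks observed covariates on the same scale.
- **Multiple imputation** — chained-equations imputation for mixed types
  (logistic draws, predictive mean matching, multinomial draws) with
  auxiliary-variable support and Rubin's-rules pooling (Barnard–Rubin df).
- **Not-At-Random tipping-point analysis** — delta-adjusted imputation of
  the exposure and/or outcome over a grid of conditional sensitivity
  parameters (log-odds 0 to −2), converted to marginal sensitivity
  parameters and prevalences among the missing, with tipping-point
  detection.

See `docs/methods.md` for the models, algorithms and their assumptions.

## Worked example

```python
from cohortsens import default_spec, simulate, run_scenarios
from cohortsens.mi_engine import MiConfig, impute, pool_logistic

spec = default_spec(preset="mothers", n=13_000)   # true log OR = ln 1.5 ≈ 0.405
table, truth = simulate(spec, seed=1)             # ~12% missing exposure/outcome

bracket = run_scenarios(table)
print(bracket.summary())

est = bracket.estimates["confounders_only"]
print(est.evalue(outcome_common=True).summary())

pooled = pool_logistic(impute(table, MiConfig(m=10, burnin=5, seed=1)),
                       "confounders_only")
print(pooled.summary())
```

prints

```
Adjustment-scenario bracketing
========================================================
unadjusted                  OR  1.868 (1.666, 2.095)  p=1.099e-26  n=10082
confounders_only            OR  1.751 (1.547, 1.983)  p=9.635e-19  n=8682
confounders_and_mediators   OR  1.692 (1.487, 1.925)  p=1.448e-15  n=8045
adjusted log-OR bracket [0.5257, 0.5604]   signs agree: True
E-value analysis
========================================
odds ratio        1.751  (common-outcome sqrt transform)
approx risk ratio 1.3234
E-value (point)   1.98
E-value (CI)      1.79
pooled log OR 0.5615 (SE 0.0625), OR 1.7533 95% CI (1.5490, 1.9845), p=1.03e-14, m=10, df=106.5
```

Reading the output: the unadjusted odds ratio (1.87) drops to 1.75 under
confounder adjustment and the two adjusted scenarios nearly coincide, so
confounder mis-specification matters little here. The adjusted estimate
(log OR ≈ 0.53–0.56) sits above the generating effect (0.405) because the
default cohort plants an unmeasured confounder; the E-value says a
confounder would need risk-ratio associations of about 2.0 with both
exposure and outcome to explain the association away entirely (1.8 to
erase significance). Multiple imputation recovers the complete-case
estimate with a narrower interval, as expected when missingness is
auxiliary-driven.

The same battery runs from the shell:

```sh
cohortsens simulate --n 13000 --seed 1 --out cohort.csv
cohortsens estimate cohort.csv
cohortsens evalue --odds-ratio 1.154 --ci-low 0.996 --ci-high 1.336
cohortsens gsa cohort.csv --grid 0.05,0.10,0.15 --k-draws 10
cohortsens tipping cohort.csv --mode both --m 10 --burnin 5
cohortsens battery --config run.yaml --out results/
```

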