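# subgroupcox

Subgroup-weighted lasso-penalized Cox regression for heterogeneous survival
cohorts.

## The problem

Risk-prediction models from high-dimensional molecular data (p >> n) are
usually wanted *per subgroup* — per study, per center, per clinical
stratum. Subgroup-only analysis throws away most of the data and loses
power when cohorts are small; pooling everything averages away
subgroup-specific effects. `subgroupcox` fits, for each target subgroup s,
a lasso-penalized Cox model on **all** patients, each carrying an
individual weight

    w_s(y, x) = p(s | y, x) / p(s),

the probability of belonging to s given covariates and survival response,
divided by the subgroup's frequency. Patients who resemble the target
subgroup contribute nearly fully; patients from clearly different
subgroups fade out. The weights are estimated from the training data by
cross-validated multi-class classification (multinomial lasso/ridge
logistic regression or random forest), so the model adapts automatically:
when subgroups are indistinguishable every weight is ~1 and the fit
approaches the pooled model; when they separate cleanly the fit approaches
the subgroup-only model.

The weighted partial log-likelihood (Breslow ties) is

    l(beta) = sum_i delta_i w_i [ beta'x_i
              - log( sum_{k: t_k >= t_i} w_k exp(beta'x_k) ) ],

maximized with an L1 penalty lambda * sum_j |beta_j|; lambda is chosen by
tenfold cross-validation of the partial-likelihood deviance. Baselines:
fixed weights w in {0.1, ..., 0.9} for all non-target patients (w = 0
recovers the subgroup-only model exactly; w = 1 the pooled model),
subgroup-only (`sub`), and pooled with subgroup-indicator covariates
(`all`). Prediction is evaluated with Harrell's concordance index.
A synthetic-cohort generator reproduces the reference study design: four
subgroups in two latent groups, Weibull event and censoring times anchored
to real lung-cancer survival fractions, and an epsilon dial in [0, 1] for
between-group covariate separation. See `docs/methods.md` for the full
model description.

## Worked example

```python
import numpy as np
from subgroupcox import (
    ModelSpec, SimulationConfig, fit_model, generate_dataset, score_fit,
)

cfg_train = SimulationConfig(n_per_subgroup=100, p=100, epsilon=0.5, seed=1)
cfg_test = SimulationConfig(n_per_subgroup=100, p=100, epsilon=0.5, seed=2)
train, test = generate_dataset(cfg_train), generate_dataset(cfg_test)

for mode, kwargs in [
    ("estimated_weights", {"classifier": "rf"}),
    ("subgroup", {}),
    ("combined", {}),
]:
    fit = fit_model(ModelSpec(mode, target_subgroup=1, **kwargs), train, seed=0)
    ci = score_fit(fit, test, target_subgroup=1)
    print(f"{mode:18s} C-index {ci:.3f}  nonzero {fit.n_nonzero:2d}  lambda {fit.lambda_:.4f}")
```

```
estimated_weights  C-index 0.805  nonzero 29  lambda 0.0457
subgroup           C-index 0.802  nonzero 47  lambda 0.0380
combined           C-index 0.745  nonzero 41  lambda 0.0337
```

At epsilon = 0.5 the two latent groups are separable, so the estimated
weights concentrate on the target group: the weighted model matches the
subgroup-only fit (it effectively doubles the usable sample, since
subgroups 1A/1B share one distribution) while the pooled model pays for
averaging the two groups' opposing gene effects.

The same menu is scriptable from the shell:

```bash
subgroupcox simulate --config cfg.json --out cohort.csv
subgroupcox weights --data cohort.csv --classifier rf --out weights.csv
subgroupcox fit --data cohort.csv --mode estimated_weights --classifier rf \
    --subgroup 1 --out coef.csv
subgroupcox experiment --config cfg.json --reps 100 --out-dir results/
```

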