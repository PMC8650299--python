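# Methods

## Problem setting

`subgroupcox` builds separate risk-prediction models for pre-known patient
subgroups (multicenter cohorts, studies, or clinically defined strata) in
right-censored, typically high-dimensional settings such as gene-expression
survival studies. The tension it addresses: subgroup-only analysis discards
most of the data and loses power at small n, while naive pooling averages
away subgroup-specific effects. The package interpolates between the two by
fitting, for each target subgroup s, a lasso-penalized Cox model on *all*
patients with individual observation weights that measure how well each
patient matches subgroup s.

## Weighted Cox partial likelihood

For patient i with observed time t_i = min(T_i, C_i), event indicator
delta_i, covariates x_i and weight w_i >= 0, the weighted partial
log-likelihood is

    l(beta) = sum_i delta_i w_i [ beta'x_i
              - log( sum_k 1(t_i <= t_k) w_k exp(beta'x_k) ) ].

The indicator `1(t_i <= t_k)` means tied event times share one risk set —
Breslow tie handling — and that convention is used in the solver, the
cross-validation criterion, and every test oracle. Efron ties, elastic-net
penalties, stratified baseline hazards and absolute survival prediction
(baseline-hazard estimation) are deliberately out of scope; the model is
used for risk ranking via the linear predictor.

## Estimated weights as density ratios

The weight of patient i in the model for subgroup s is

    w_s(y, x) = p(y, x | s) / p(y, x) = p(s | y, x) / p(s),

the posterior probability of belonging to s given covariates and response,
over the subgroup's empirical frequency. This identity rewrites the
subgroup-specific expected loss as a weighted expectation under the pooled
distribution, so the weighted fit targets the subgroup's own population
while borrowing every informative patient. The posterior is a multi-class
classification problem: the classifier sees the covariates augmented by the
survival response, encoded as (log t_i, delta_i) — log time because the
hazard model is multiplicative in time. Posteriors are estimated
*out-of-fold* with 10-fold cross-validation (folds stratified by subgroup)
to avoid the optimism of resubstitution; a single fold partition is shared
across classifiers so classifier comparisons are not confounded by fold
noise.

Three classifiers are provided:

| name   | model                               | tuning                                  |
|--------|-------------------------------------|-----------------------------------------|
| lasso  | multinomial logistic, L1            | penalty by nested 10-fold CV (8 C values, log-loss) |
| ridge  | multinomial logistic, L2            | same                                     |
| rf     | random forest, 500 trees            | none; minimum node size 10 (probability-forest convention) |

The ratios are not truncated or renormalized here — they may exceed 1, and
a patient from a small subgroup can receive a large weight. The Cox fitter
normalizes whatever weights it receives to sum to one, which provably
leaves the estimate invariant to any global rescaling.

Fixed-weight baselines assign weight 1 to the target subgroup and a
constant w in [0, 1] to everyone else; w = 0 recovers the subgroup-only
model and w = 1 the pooled model, both exactly (see below).

## Solver

The estimator maximizes `l(beta) - lambda * sum_j |beta_j|` with weights
normalized to sum to one (the same reparameterization glmnet performs by
rescaling weights to the sample size). The algorithm is the standard
penalized-Cox recipe: iteratively reweighted least squares around the
current linear predictor using the gradient and diagonal Hessian of the
Breslow log-likelihood, with cyclic coordinate descent and
soft-thresholding on the weighted working response. Numerical choices:

* Covariates are standardized internally with weighted means/variances and
  coefficients reported on the original scale; zero-variance columns stay
  at zero.
* Zero-weight rows are removed before any arithmetic, which makes "weight
  zero" and "row deleted" produce bitwise-identical results.
* lambda grid: 100 log-spaced values from lambda_max (the smallest penalty
  with an all-zero solution, computed from the weighted score at beta = 0)
  down to lambda_max * 1e-2 when n <= p, else lambda_max * 1e-4.
* Convergence: coordinate-descent tolerance 1e-7 on the largest coefficient
  change (at most 1e5 sweeps per subproblem); outer IRLS stops on a
  stationary coefficient vector or a stationary objective. Step halving
  keeps the ascent monotone. A fit still improving at the iteration cap is
  a saturated (quasi-separable) partial likelihood whose supremum is only
  approached asymptotically; the current iterate is returned, matching
  glmnet's maxit behavior. Warm-started path walks additionally stop early
  once an extra lambda step improves the normalized log-likelihood by less
  than 1e-5 (relative to the null fit) or stops converging within its
  per-step budget — the remaining smaller lambdas inherit the saturated
  solution, which cross-validation never selects anyway.
* Coefficients with magnitude below 1e-12 are reported as exactly zero so
  sparsity counts are reproducible.

The penalty is chosen by 10-fold cross-validation of the
Verweij–van Houwelingen partial-likelihood deviance: for each fold,
-2 [ l_full(beta_fold) - l_train(beta_fold) ], summed over folds on one
shared lambda grid, with the minimizing lambda selected. Held-out patients
keep their weights. Folds are stratified by event indicator (preventing
event-free folds at small n) and are assigned over positive-weight rows
only; zero-weight rows sit in every training part. That last detail is what
makes the fixed-weight w = 0 model equal the subgroup-only model *through
the entire CV path*, not just at a common lambda.

Two open choices were resolved as follows. The CV performance measure is
the partial-likelihood deviance (the standard for penalized Cox; the
alternative — concordance — is noisier at small n). In the pooled model the
S-1 subgroup-indicator dummies (reference: first label) are penalized like
every other column; forcing them in would privilege the indicator in a way
nothing in the design motivates, and uniform treatment keeps the design
matrix homogeneous.

## Synthetic cohorts

The generator emulates a four-subgroup (1A, 1B, 2A, 2B), two-latent-group
gene-expression survival study; subgroups within a group are i.i.d.

* Covariates: p i.i.d. normal "genes" with identity covariance. Group
  means follow three tiers tied to each group's own effect vector:
  mu = 4 + 4 epsilon for |beta| = 1, mu = 4 + 2 epsilon for
  |beta| in {0.5, 0.75}, mu = 4 otherwise, mimicking log2-scale expression
  where prognostic genes sit above the noise floor. epsilon in [0, 1] is
  the between-group separation dial: at 0 the groups are exchangeable in
  their covariates; at 1 strong-effect genes differ by 4 SDs. Since genes
  9–12 carry identical effects in both groups, their means always agree.
* Effects: a canonical 12-gene table — subgroup-specific (genes 1–4),
  opposite (5–6), same-direction different-size (7–8), and joint (9–12)
  effects, summing to zero within each group; genes beyond 12 are noise.
* Survival: event times by Weibull inverse transform
  T = (-log U / (eta exp(x'beta)))^(1/kappa). The two groups' baseline
  (eta, kappa) are solved in closed form from 3-/5-year Kaplan–Meier
  survival anchors of two real lung-cancer cohorts — (57%, 42%) for group 1
  and (75%, 62%) for group 2 (the assignment of anchor pair to group is a
  labeling convention; results are symmetric under relabeling).
* Censoring: C is drawn from the *same* mechanism — same eta, kappa and
  linear predictor, independent uniform. This is the only reading of
  "censoring with the same parameters" that yields the intended ~50%
  censoring for every patient regardless of covariates, by exact symmetry
  of two i.i.d. draws.

What the generator does not emulate: correlated genes (a correlated option
was evaluated upstream of this design and made no material difference, so
identity covariance is used), unequal subgroup sizes, non-Weibull or
informative censoring, and measurement artifacts of real expression data
(batch effects, heavy tails, missingness). Tests passing on these cohorts
therefore demonstrate correctness of the estimators and the qualitative
regimes (pooling helps at small n; estimated weights adapt to separation),
not performance on any particular real cohort.

## Evaluation

Harrell's C-index with the classical usable-pair rules: a pair (i, i*)
counts iff delta_i = 1 and t_{i*} > t_i strictly — two simultaneous deaths,
two censored patients, or a censoring before the other's death are
unusable; risk-score ties contribute 1/2. An event and a censoring at the
same time are unusable (strict inequality, implemented literally). With no
usable pair the index is undefined and an error is raised rather than 0.5.
No inverse-probability-of-censoring weighting and no truncation horizon.

## Experiment pipeline

Each replicate draws fresh, independent training and test cohorts of the
same size and distribution (for real data: one stratified split with
training fraction 0.632, stratified by subgroup x event indicator), fits
the 14-model menu — three estimated-weights models, nine fixed weights
(0.1–0.9), subgroup-only, pooled-with-indicator — and scores every model on
the target subgroup's test rows only. Weights, lambda and coefficients are
computed from training rows alone. A master seed spawns per-replicate
substreams, so replicates are independent, individually reproducible, and
identical whether run serially or in parallel. Failed replicates are
recorded as missing (excluded pairwise from means); more than 20% failures
abort the run. Mean C-indexes per model and mean inclusion frequencies
(fraction of replicates in which a covariate gets a nonzero coefficient)
are the summary outputs.

## Problem sizes in the shipped checks

The replicated-ordering checks run 25 replicates per scenario: the
small-sample regime at n = 20 per subgroup with p = 100 noise-heavy genes
(epsilon 0), and the large-sample regime at n = 200 per subgroup with
p = 12 (epsilon 0.5) using the rf classifier; n = 200 is the point in the
study grid where the large-n conclusions are already stable, and the three
classifiers behave near-identically in this regime. Classifier-separation
and weight-calibration checks use n = p = 100 per subgroup averaged over 10
seeds; Monte-Carlo calibration checks use 10,000–100,000 draws. These sizes
are the package's reference configurations; the library itself accepts the
full grid (n up to 1000 per subgroup, p up to 200, epsilon up to 1 — 252
scenarios).

## Known limitations

* Weight quality inherits the classifier's calibration; badly calibrated
  posteriors (e.g. random forests on tiny samples) bias weights even when
  discrimination is good.
* Subgroups must be pre-known and unique per patient; discovering latent
  subgroups is out of scope.
* The C-index depends on the censoring distribution; comparisons across
  cohorts with very different censoring should use censoring-adjusted
  variants, which this package intentionally does not implement.
* The solver targets p up to a few hundred (dense arithmetic); it is not
  tuned for p in the tens of thousands without prior feature filtering.
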