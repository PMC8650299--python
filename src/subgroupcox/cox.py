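"""Weighted Cox partial likelihood with lasso penalization.

The subgroup-specific model includes *all* patients in the partial
likelihood, each with an individual nonnegative weight w_i:

    l(beta) = sum_i delta_i w_i [beta' x_i
              - log(sum_k 1(t_i <= t_k) w_k exp(beta' x_k))]

The indicator ``1(t_i <= t_k)`` makes tied event times share their risk set
(Breslow handling), and that convention is used everywhere, including the
cross-validation criterion.

Estimation maximizes ``l(beta) - lambda * sum_j |beta_j|`` with the weights
normalized to sum to one (the same reparameterization glmnet applies by
rescaling weights to the sample size), which makes the fit invariant to a
global rescaling of the weights and keeps lambda comparable across
weighting schemes and cohort sizes. The solver follows the glmnet recipe: iteratively
reweighted least squares around the current linear predictor, with cyclic
coordinate descent and soft-thresholding on the weighted working response;
covariates are standardized internally (weighted mean/variance) and
coefficients reported on the original scale. The penalty level is chosen by
k-fold cross-validation of the Verweij-van-Houwelingen partial-likelihood
deviance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data import SubgroupedSurvivalData

__all__ = [
    "CoxLassoFit",
    "ModelSpec",
    "FitError",
    "ConvergenceError",
    "weighted_cox_loglik",
    "fit_weighted_cox_lasso",
    "select_lambda_cv",
    "fixed_weight_vector",
    "fit_model",
    "write_fit",
]

logger = logging.getLogger(__name__)

CD_TOL = 1e-7           # max |coefficient change| per coordinate-descent sweep
MAX_CD_PASSES = 100_000
MAX_IRLS_ITER = 100
ZERO_THRESHOLD = 1e-12  # coefficients below this magnitude are reported as 0
N_LAMBDA = 100


class FitError(RuntimeError):
    """Raised when a fit is impossible (e.g. no usable weighted events)."""


class ConvergenceError(RuntimeError):
    """Raised when the solver exhausts its iteration budget."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


# ---------------------------------------------------------------------------
# likelihood


def _check_weights(n: int, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != n:
        raise ValueError(f"weights must have length n={n}, got {w.shape[0]}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w


def _tie_bounds(times_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    first = np.searchsorted(times_sorted, times_sorted, side="left")
    last = np.searchsorted(times_sorted, times_sorted, side="right") - 1
    return first.astype(np.int64), last.astype(np.int64)


def _loglik_arrays(times, events, x, weights, beta) -> float:
    """Weighted Breslow partial log-likelihood on plain arrays.

    Zero-weight rows are dropped up front: they contribute nothing, and
    removing them makes the arithmetic bitwise identical to the same call
    on the positive-weight rows alone.
    """
    pos = weights > 0
    if not pos.all():
        times, events, x, weights = times[pos], events[pos], x[pos], weights[pos]
    d = events * weights
    if not np.any(d > 0):
        return 0.0
    order = np.argsort(times, kind="stable")
    t = times[order]
    dw = d[order]
    eta = x[order] @ beta
    w = weights[order]
    first, _ = _tie_bounds(t)
    c = eta.max()
    wexp = w * np.exp(eta - c)
    # suffix sums of w_k exp(eta_k) over the risk set {k: t_k >= t_i}
    suffix = np.concatenate([np.cumsum(wexp[::-1])[::-1], [0.0]])
    ev = dw > 0
    denom = suffix[first[ev]]
    return float(np.sum(dw[ev] * (eta[ev] - (np.log(denom) + c))))


def weighted_cox_loglik(beta, data: SubgroupedSurvivalData, weights) -> float:
    """Evaluate the weighted partial log-likelihood at ``beta``.

    With all weights equal to 1 this is the standard Breslow partial
    log-likelihood; when no event carries positive weight the empty sum 0 is
    returned.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.p:
        raise ValueError(f"beta must have length p={data.p}, got {beta.shape[0]}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    w = _check_weights(data.n, weights)
    return _loglik_arrays(data.times, data.events.astype(float), data.covariates, w, beta)


# ---------------------------------------------------------------------------
# solver kernels


@njit(cache=True)
def _grad_hess(eta, w, delta, tie_first, tie_last):  # pragma: no cover - jit
    """Gradient/diagonal Hessian of the weighted Breslow log-likelihood wrt eta."""
    n = eta.shape[0]
    c = eta[0]
    for i in range(1, n):
        if eta[i] > c:
            c = eta[i]
    wexp = np.empty(n)
    for i in range(n):
        wexp[i] = w[i] * math.exp(eta[i] - c)
    suffix = np.empty(n + 1)
    suffix[n] = 0.0
    for j in range(n - 1, -1, -1):
        suffix[j] = suffix[j + 1] + wexp[j]
    e1 = np.zeros(n)
    e2 = np.zeros(n)
    ll = 0.0
    for i in range(n):
        dw = delta[i] * w[i]
        if dw > 0.0:
            denom = suffix[tie_first[i]]
            e1[i] = dw / denom
            e2[i] = dw / (denom * denom)
            ll += dw * (eta[i] - (math.log(denom) + c))
    acc1 = 0.0
    acc2 = 0.0
    ce1 = np.empty(n)
    ce2 = np.empty(n)
    for i in range(n):
        acc1 += e1[i]
        acc2 += e2[i]
        ce1[i] = acc1
        ce2[i] = acc2
    g = np.empty(n)
    h = np.empty(n)
    for r in range(n):
        a = ce1[tie_last[r]]
        b = ce2[tie_last[r]]
        g[r] = delta[r] * w[r] - wexp[r] * a
        hr = wexp[r] * a - wexp[r] * wexp[r] * b
        h[r] = hr if hr > 0.0 else 0.0
    return g, h, ll


@njit(cache=True)
def _cd_lasso(x, h, z, beta, lam, tol, max_passes):  # pragma: no cover - jit
    """Cyclic coordinate descent for (1/2) sum h (z - x b)^2 + lam * ||b||_1.

    The IRLS weights h already carry the (sum-to-one) observation-weight
    scale, so no explicit 1/n factor appears.
    """
    n, p = x.shape
    res = np.empty(n)
    for r in range(n):
        acc = z[r]
        for j in range(p):
            if beta[j] != 0.0:
                acc -= x[r, j] * beta[j]
        res[r] = acc
    hxx = np.empty(p)
    for j in range(p):
        s = 0.0
        for r in range(n):
            s += h[r] * x[r, j] * x[r, j]
        hxx[j] = s
    n_pass = 0
    for _ in range(max_passes):
        n_pass += 1
        max_delta = 0.0
        for j in range(p):
            if hxx[j] <= 0.0:
                continue
            grad = 0.0
            for r in range(n):
                grad += h[r] * x[r, j] * res[r]
            grad = grad + hxx[j] * beta[j]
            if grad > lam:
                bnew = (grad - lam) / hxx[j]
            elif grad < -lam:
                bnew = (grad + lam) / hxx[j]
            else:
                bnew = 0.0
            d = bnew - beta[j]
            if d != 0.0:
                for r in range(n):
                    res[r] -= d * x[r, j]
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            break
    return beta, n_pass


# ---------------------------------------------------------------------------
# fitting


@dataclass
class _Prep:
    """Sorted/standardized problem arrays for one fit."""

    xs: np.ndarray          # standardized covariates, rows sorted by time
    w: np.ndarray           # weights normalized to sum 1, sorted
    delta: np.ndarray       # event indicators, sorted
    tie_first: np.ndarray
    tie_last: np.ndarray
    mean: np.ndarray
    sd: np.ndarray          # 1.0 for zero-variance columns (column zeroed)
    w_norm_unsorted: np.ndarray
    n: int
    p: int


def _prepare(times, events, x, weights) -> _Prep:
    """Filter zero-weight rows, normalize weights to sum 1, standardize, sort.

    Dropping zero-weight rows before any arithmetic makes "weight zero" and
    "row deleted" bitwise-identical problems; normalizing to sum 1 (rather
    than to a row count) removes every dependence on how many zero rows the
    input carried.
    """
    n_full, p = x.shape
    total = weights.sum()
    if total <= 0:
        raise FitError("all weights are zero")
    pos = weights > 0
    times, events, x, w = times[pos], events[pos], x[pos], weights[pos]
    w_hat = w / total
    delta = events.astype(float)
    if not np.any(delta * w_hat > 0):
        raise FitError("no event carries positive weight; nothing to fit")
    mean = w_hat @ x
    var = w_hat @ (x - mean) ** 2
    sd = np.sqrt(var)
    degenerate = sd <= 0
    sd = np.where(degenerate, 1.0, sd)
    xs = (x - mean) / sd
    if degenerate.any():
        xs[:, degenerate] = 0.0
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    first, last = _tie_bounds(t_sorted)
    return _Prep(
        xs=np.ascontiguousarray(xs[order]),
        w=w_hat[order],
        delta=delta[order],
        tie_first=first,
        tie_last=last,
        mean=mean,
        sd=sd,
        w_norm_unsorted=weights * (n_full / total),
        n=int(pos.sum()),
        p=p,
    )


def _lambda_max(prep: _Prep) -> float:
    g0, _, _ = _grad_hess(
        np.zeros(prep.n), prep.w, prep.delta, prep.tie_first, prep.tie_last
    )
    score = prep.xs.T @ g0
    lam = float(np.max(np.abs(score)))
    return max(lam, 1e-10)


def _lambda_grid(lam_max: float, n: int, p: int, n_lambda: int = N_LAMBDA) -> np.ndarray:
    ratio = 1e-2 if n <= p else 1e-4
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_at_lambda(
    prep: _Prep, lam: float, beta: np.ndarray, max_iter: int = MAX_IRLS_ITER
) -> tuple[np.ndarray, float, bool]:
    """IRLS around eta = Xs beta, with objective-based step halving.

    Returns ``(beta, loglik, converged)``. Step halving keeps the ascent
    monotone, so a fit still improving at the iteration cap is a saturated
    or quasi-separable likelihood whose supremum is approached only
    asymptotically; the current iterate is returned with ``converged=False``
    (glmnet's maxit behavior). A step that cannot improve the objective at
    all raises ConvergenceError.
    """
    beta = beta.copy()
    eta = prep.xs @ beta
    g, h, ll = _grad_hess(eta, prep.w, prep.delta, prep.tie_first, prep.tie_last)
    obj = ll - lam * np.abs(beta).sum()
    gain = np.inf
    for it in range(max_iter):
        pos = h > 1e-12
        z = np.where(pos, eta + g / np.where(pos, h, 1.0), eta)
        hz = np.where(pos, h, 0.0)
        beta_new, _ = _cd_lasso(
            prep.xs, hz, z, beta.copy(), lam, CD_TOL, MAX_CD_PASSES
        )
        accepted = False
        for _ in range(40):
            eta_new = prep.xs @ beta_new
            if np.max(np.abs(eta_new)) > 250:
                beta_new = 0.5 * (beta + beta_new)
                continue
            g2, h2, ll2 = _grad_hess(
                eta_new, prep.w, prep.delta, prep.tie_first, prep.tie_last
            )
            obj_new = ll2 - lam * np.abs(beta_new).sum()
            if obj_new >= obj - 1e-12:
                accepted = True
                break
            beta_new = 0.5 * (beta + beta_new)
        if not accepted:
            raise ConvergenceError("IRLS step could not improve the objective", it + 1)
        step = np.max(np.abs(beta_new - beta)) if prep.p else 0.0
        gain = obj_new - obj
        beta, eta, g, h, ll, obj = beta_new, eta_new, g2, h2, ll2, obj_new
        # stop on a stationary coefficient vector, or on a stationary
        # objective (saturated / quasi-separable likelihoods plateau while
        # the coefficients drift)
        if step < CD_TOL or gain < 1e-9 * (abs(obj) + 1.0):
            return beta, ll, True
    return beta, ll, False


# relative deviance-improvement threshold below which the path stops early
# (the remaining, smaller lambdas inherit the saturated solution)
PATH_FDEV = 1e-5
# IRLS iteration budget per grid point while walking a warm-started path
PATH_MAX_ITER = 25


def _fit_path(
    prep: _Prep, lambdas: np.ndarray, early_stop: bool = True
) -> np.ndarray:
    """Warm-started coefficient path (standardized scale), one row per lambda.

    With ``early_stop`` (used during cross-validation), descending the grid
    stops once an extra lambda step no longer improves the mean
    log-likelihood noticeably, or once a grid point fails to converge within
    its iteration budget (a quasi-separable plateau); later grid points
    reuse the last solution.
    """
    betas = np.zeros((len(lambdas), prep.p))
    beta = np.zeros(prep.p)
    _, _, ll_null = _grad_hess(
        np.zeros(prep.n), prep.w, prep.delta, prep.tie_first, prep.tie_last
    )
    ll_prev = ll_null
    for i, lam in enumerate(lambdas):
        beta, ll, converged = _fit_at_lambda(prep, float(lam), beta, PATH_MAX_ITER)
        betas[i] = beta
        saturated = ll - ll_prev < PATH_FDEV * (abs(ll_null) + 1.0)
        if early_stop and ((i > 0 and saturated) or not converged):
            betas[i + 1 :] = beta
            break
        ll_prev = ll
    return betas


def _to_original_scale(beta_std: np.ndarray, prep: _Prep) -> np.ndarray:
    coef = beta_std / prep.sd
    coef[np.abs(coef) < ZERO_THRESHOLD] = 0.0
    return coef


@dataclass
class CoxLassoFit:
    """Result of a lasso-penalized weighted Cox fit.

    ``coefficients`` are on the original covariate scale; ``weights_used``
    are the internally normalized weights (they sum to n); ``cv_curve`` holds
    (lambda, CV deviance) pairs when the penalty was cross-validated.
    """

    coefficients: np.ndarray
    lambda_: float
    weights_used: np.ndarray
    cv_curve: list[tuple[float, float]] = field(default_factory=list)
    n_nonzero: int = 0
    feature_names: tuple[str, ...] | None = None
    mode: str | None = None
    target_subgroup: int | None = None
    classifier: str | None = None
    seed: int | None = None
    dummy_levels: tuple[int, ...] | None = None
    reference_level: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.n_nonzero = int(np.sum(np.abs(self.coefficients) >= ZERO_THRESHOLD))


def fit_weighted_cox_lasso(
    data: SubgroupedSurvivalData, weights, lambda_: float
) -> CoxLassoFit:
    """Fit the weighted Cox model with an L1 penalty at a fixed lambda.

    For numerical robustness the solver warm-starts along a short path from
    the all-zero solution at lambda_max down to the requested penalty. Any
    lambda at or above lambda_max returns an exactly zero coefficient vector.
    Zero-weight patients have no influence on the estimate.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    w = _check_weights(data.n, weights)
    prep = _prepare(data.times, data.events, data.covariates, w)
    lam_max = _lambda_max(prep)
    if lambda_ >= lam_max:
        beta_std = np.zeros(prep.p)
    else:
        if lambda_ > 0:
            path = np.geomspace(lam_max, lambda_, 30)
        else:
            path = np.append(np.geomspace(lam_max, lam_max * 1e-4, 30), 0.0)
        warm = _fit_path(prep, path, early_stop=False)[-1]
        beta_std, _, converged = _fit_at_lambda(prep, float(lambda_), warm)
        if not converged:
            warnings.warn(
                "fit stopped at the iteration cap with the likelihood still "
                "improving (saturated or quasi-separable data)"
            )
    return CoxLassoFit(
        coefficients=_to_original_scale(beta_std, prep),
        lambda_=float(lambda_),
        weights_used=prep.w_norm_unsorted,
        feature_names=data.covariate_names,
    )


# ---------------------------------------------------------------------------
# cross-validated penalty selection


def _assign_folds(events, weights, n_folds, seed) -> np.ndarray:
    """Event-stratified fold ids over positive-weight rows (-1 elsewhere).

    The assignment depends only on the relative order of the positive-weight
    rows within each event stratum, so a dataset and its zero-weight-padded
    counterpart receive identical folds under the same seed.
    """
    rng = np.random.default_rng(seed)
    fold_of = np.full(events.shape[0], -1, dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero((events == value) & (weights > 0))
        perm = rng.permutation(idx.shape[0])
        fold_of[idx[perm]] = np.arange(idx.shape[0]) % n_folds
    return fold_of


def _cv_select(
    data: SubgroupedSurvivalData, weights, n_folds: int, seed: int
) -> tuple[float, list[tuple[float, float]]]:
    w = _check_weights(data.n, weights)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    prep_full = _prepare(data.times, data.events, data.covariates, w)
    grid = _lambda_grid(_lambda_max(prep_full), prep_full.n, prep_full.p)
    fold_of = _assign_folds(data.events, w, n_folds, seed)
    deviance = np.zeros(len(grid))
    n_used = 0
    x = data.covariates
    ev = data.events.astype(float)
    for f in range(n_folds):
        train = fold_of != f
        try:
            prep_f = _prepare(data.times[train], data.events[train], x[train], w[train])
        except FitError:
            warnings.warn(f"CV fold {f} has no weighted events; skipping")
            continue
        betas = _fit_path(prep_f, grid)
        for i in range(len(grid)):
            coef = _to_original_scale(betas[i], prep_f)
            ll_full = _loglik_arrays(data.times, ev, x, w, coef)
            ll_train = _loglik_arrays(
                data.times[train], ev[train], x[train], w[train], coef
            )
            deviance[i] += -2.0 * (ll_full - ll_train)
        n_used += 1
    if n_used == 0:
        raise FitError("every CV fold was skipped; cannot select lambda")
    best = int(np.argmin(deviance))
    curve = [(float(l), float(d)) for l, d in zip(grid, deviance)]
    return float(grid[best]), curve


def select_lambda_cv(
    data: SubgroupedSurvivalData, weights, n_folds: int = 10, seed: int = 0
) -> float:
    """Pick lambda minimizing the k-fold weighted partial-likelihood deviance.

    The criterion is the Verweij-van-Houwelingen construction: for each fold,
    -2 times the difference between the full-data and the training-part
    log-likelihood at the fold estimate, summed over folds on a shared
    log-spaced lambda grid. Held-out patients keep their weights. Fold
    assignment is stratified by event indicator and deterministic given seed.
    """
    lam, _ = _cv_select(data, weights, n_folds, seed)
    return lam


# ---------------------------------------------------------------------------
# model constructions


def fixed_weight_vector(
    data: SubgroupedSurvivalData, target_subgroup: int, w: float
) -> np.ndarray:
    """Weight 1 for the target subgroup, constant w in [0, 1] for the rest.

    w=0 recovers the subgroup-only analysis, w=1 the pooled analysis.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("fixed weight w must lie in [0, 1]")
    if not np.any(data.subgroups == target_subgroup):
        raise ValueError(f"subgroup {target_subgroup} absent from data")
    return np.where(data.subgroups == target_subgroup, 1.0, float(w))


_MODES = ("estimated_weights", "fixed_weights", "subgroup", "combined")
_CLASSIFIERS = ("lasso", "ridge", "rf")


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four model constructions to fit, and for which subgroup."""

    mode: str
    target_subgroup: int = 1
    fixed_w: float | None = None
    classifier: str | None = None
    include_subgroup_indicator: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode == "fixed_weights":
            if self.fixed_w is None:
                raise ValueError("fixed_weights mode requires fixed_w")
            if not (0.0 <= self.fixed_w <= 1.0):
                raise ValueError("fixed_w must lie in [0, 1]")
        elif self.fixed_w is not None:
            raise ValueError("fixed_w is only valid in fixed_weights mode")
        if self.mode == "estimated_weights":
            if self.classifier not in _CLASSIFIERS:
                raise ValueError(f"classifier must be one of {_CLASSIFIERS}")
        elif self.classifier is not None:
            raise ValueError("classifier is only valid in estimated_weights mode")


def _fit_with_cv(data, weights, seed, n_folds) -> CoxLassoFit:
    lam, curve = _cv_select(data, weights, n_folds, seed)
    fit = fit_weighted_cox_lasso(data, weights, lam)
    fit.cv_curve = curve
    return fit


def fit_model(
    spec: ModelSpec,
    data: SubgroupedSurvivalData,
    seed: int = 0,
    n_folds: int = 10,
    weight_matrix=None,
) -> CoxLassoFit:
    """Fit one entry of the model menu; lambda is always chosen by CV.

    ``weight_matrix`` may carry a precomputed :class:`~subgroupcox.weights.
    WeightMatrix` for estimated_weights mode (the pipeline reuses one matrix
    across subgroups); otherwise weights are estimated here.
    """
    s = spec.target_subgroup
    if not np.any(data.subgroups == s):
        raise ValueError(f"target subgroup {s} absent from data")
    if spec.mode == "subgroup":
        idx = np.flatnonzero(data.subgroups == s)
        sub = data.subset(idx, relabel=True)
        fit = _fit_with_cv(sub, np.ones(sub.n), seed, n_folds)
    elif spec.mode == "fixed_weights":
        w = fixed_weight_vector(data, s, spec.fixed_w)
        fit = _fit_with_cv(data, w, seed, n_folds)
    elif spec.mode == "estimated_weights":
        if weight_matrix is None:
            from .weights import estimate_weight_matrix

            weight_matrix = estimate_weight_matrix(
                data, classifier=spec.classifier, seed=seed
            )
        w = weight_matrix.values[:, s - 1]
        fit = _fit_with_cv(data, w, seed, n_folds)
    else:  # combined
        aug = data
        dummy_levels: tuple[int, ...] = ()
        if spec.include_subgroup_indicator and data.n_subgroups > 1:
            dummy_levels = tuple(range(2, data.n_subgroups + 1))
            dummies = np.column_stack(
                [(data.subgroups == lev).astype(float) for lev in dummy_levels]
            )
            aug = SubgroupedSurvivalData(
                times=data.times,
                events=data.events,
                subgroups=data.subgroups,
                covariates=np.hstack([data.covariates, dummies]),
                covariate_names=data.covariate_names
                + tuple(f"subgroup_{lev}" for lev in dummy_levels),
            )
        fit = _fit_with_cv(aug, np.ones(aug.n), seed, n_folds)
        fit.dummy_levels = dummy_levels or None
        fit.reference_level = 1 if dummy_levels else None
    fit.mode = spec.mode
    fit.target_subgroup = s
    fit.classifier = spec.classifier
    fit.seed = seed
    return fit


# ---------------------------------------------------------------------------
# I/O


def write_fit(fit: CoxLassoFit, csv_path, json_path=None) -> None:
    """Write coefficients as CSV (name, coefficient) plus a JSON sidecar."""
    import json

    import pandas as pd

    names = fit.feature_names or tuple(
        f"x{j + 1}" for j in range(fit.coefficients.shape[0])
    )
    pd.DataFrame({"name": names, "coefficient": fit.coefficients}).to_csv(
        csv_path, index=False
    )
    if json_path is not None:
        payload = {
            "lambda": fit.lambda_,
            "mode": fit.mode,
            "target_subgroup": fit.target_subgroup,
            "classifier": fit.classifier,
            "seed": fit.seed,
            "n_nonzero": fit.n_nonzero,
            "cv_curve": fit.cv_curve,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
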