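"""Replicated experiment loop over the full model menu.

One replicate draws (or splits off) a training and a test cohort, estimates
individual subgroup weights on the training data only, fits every requested
Cox model per subgroup, and scores each fit with the C-index on the test
rows of that subgroup. The default menu holds the 14 model variants:
three estimated-weights models (one per classifier), nine fixed-weight
models (w = 0.1 .. 0.9), the subgroup-only model (``sub``) and the pooled
model with subgroup-indicator covariates (``all``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cox import CoxLassoFit, ModelSpec, fit_model
from .data import SubgroupedSurvivalData
from .evaluate import score_fit
from .simulate import SimulationConfig, generate_dataset
from .weights import CLASSIFIERS, assign_subgroup_folds, estimate_weight_matrix

__all__ = [
    "MODEL_MENU",
    "ExperimentResult",
    "stratified_split",
    "run_simulation_experiment",
    "run_real_data_experiment",
]

logger = logging.getLogger(__name__)

MODEL_MENU = (
    "lasso",
    "ridge",
    "rf",
    "w=0.1",
    "w=0.2",
    "w=0.3",
    "w=0.4",
    "w=0.5",
    "w=0.6",
    "w=0.7",
    "w=0.8",
    "w=0.9",
    "sub",
    "all",
)


def model_spec_for(name: str, target_subgroup: int) -> ModelSpec:
    """Translate a menu name into a ModelSpec for one target subgroup."""
    if name in CLASSIFIERS:
        return ModelSpec("estimated_weights", target_subgroup, classifier=name)
    if name.startswith("w="):
        return ModelSpec("fixed_weights", target_subgroup, fixed_w=float(name[2:]))
    if name == "sub":
        return ModelSpec("subgroup", target_subgroup)
    if name == "all":
        return ModelSpec("combined", target_subgroup)
    raise ValueError(f"unknown model name {name!r}")


@dataclass
class ExperimentResult:
    """Tidy per-(replicate, subgroup, model) records plus coefficient table.

    ``records`` columns: replicate, subgroup, model, cindex, n_nonzero,
    lambda. ``coefficients`` repeats the key columns followed by one column
    per covariate (combined-mode dummy columns are dropped so all models
    share the covariate axis).
    """

    records: pd.DataFrame
    coefficients: pd.DataFrame
    n_failed: int = 0

    def mean_cindex(self, by=("model",)) -> pd.Series:
        """Mean C-index aggregated over replicates (missing excluded pairwise)."""
        return self.records.groupby(list(by))["cindex"].mean()

    def mif(self, model: str | None = None, subgroup: int | None = None) -> pd.Series:
        """Mean inclusion frequency: fraction of replicates selecting each covariate."""
        df = self.coefficients
        if model is not None:
            df = df[df["model"] == model]
        if subgroup is not None:
            df = df[df["subgroup"] == subgroup]
        cov_cols = [c for c in df.columns if c not in ("replicate", "subgroup", "model")]
        return (df[cov_cols] != 0.0).mean()


def stratified_split(
    data: SubgroupedSurvivalData,
    train_fraction: float = 0.632,
    seed: int = 0,
) -> tuple[SubgroupedSurvivalData, SubgroupedSurvivalData]:
    """Split rows into train/test, stratified by subgroup x event indicator.

    Within each stratum, round(train_fraction * size) rows go to training.
    Strata with fewer than 2 rows go entirely to training (with a warning).
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for s in range(1, data.n_subgroups + 1):
        for ev in (1, 0):
            cell = np.flatnonzero((data.subgroups == s) & (data.events == ev))
            if cell.shape[0] == 0:
                continue
            if cell.shape[0] < 2:
                warnings.warn(
                    f"stratum (subgroup={s}, event={ev}) has a single row; "
                    "assigning it to training"
                )
                train_idx.append(cell)
                continue
            perm = rng.permutation(cell.shape[0])
            k = int(round(train_fraction * cell.shape[0]))
            train_idx.append(cell[perm[:k]])
            test_idx.append(cell[perm[k:]])
    train = np.sort(np.concatenate(train_idx))
    test = (
        np.sort(np.concatenate(test_idx)) if test_idx else np.empty(0, dtype=int)
    )
    return data.subset(train), data.subset(test)


def _run_replicate(
    train: SubgroupedSurvivalData,
    test: SubgroupedSurvivalData,
    models: tuple[str, ...],
    seed: int,
    replicate: int,
    n_folds: int = 10,
) -> tuple[list[dict], list[dict]]:
    """Fit and score all requested models on one train/test pair.

    Weight estimation, lambda selection and fitting use the training rows
    only; the test data enter solely through the C-index.
    """
    classifiers = [m for m in models if m in CLASSIFIERS]
    weight_matrices = {}
    if classifiers:
        # one shared fold partition so classifier comparisons share fold noise
        fold_ids = assign_subgroup_folds(train.subgroups, n_folds, seed)
        for name in classifiers:
            weight_matrices[name] = estimate_weight_matrix(
                train, classifier=name, n_folds=n_folds, seed=seed, fold_ids=fold_ids
            )
    p = train.p
    cov_names = train.covariate_names
    records: list[dict] = []
    coef_rows: list[dict] = []
    combined_fit: CoxLassoFit | None = None
    for s in range(1, train.n_subgroups + 1):
        for name in models:
            spec = model_spec_for(name, s)
            if name == "all":
                if combined_fit is None:
                    combined_fit = fit_model(spec, train, seed=seed, n_folds=n_folds)
                fit = combined_fit
            else:
                fit = fit_model(
                    spec,
                    train,
                    seed=seed,
                    n_folds=n_folds,
                    weight_matrix=weight_matrices.get(name),
                )
            ci = score_fit(fit, test, s)
            records.append(
                {
                    "replicate": replicate,
                    "subgroup": s,
                    "model": name,
                    "cindex": ci,
                    "n_nonzero": fit.n_nonzero,
                    "lambda": fit.lambda_,
                }
            )
            row = {"replicate": replicate, "subgroup": s, "model": name}
            row.update(dict(zip(cov_names, fit.coefficients[:p])))
            coef_rows.append(row)
            logger.info(
                "replicate=%d subgroup=%d model=%s cindex=%.4f nnz=%d",
                replicate,
                s,
                name,
                ci,
                fit.n_nonzero,
            )
    return records, coef_rows


def _collect(results, n_reps) -> ExperimentResult:
    records: list[dict] = []
    coefs: list[dict] = []
    n_failed = 0
    for out in results:
        if out is None:
            n_failed += 1
            continue
        rec, coef = out
        records.extend(rec)
        coefs.extend(coef)
    if n_failed > 0.2 * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} replicates failed; aborting the experiment"
        )
    return ExperimentResult(
        records=pd.DataFrame(records),
        coefficients=pd.DataFrame(coefs),
        n_failed=n_failed,
    )


def _replicate_seeds(seed: int, n_reps: int) -> list[tuple[int, int, int]]:
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_reps):
        a, b, c = (int(v) & 0x7FFFFFFF for v in child.generate_state(3))
        out.append((a, b, c))
    return out


def run_simulation_experiment(
    config: SimulationConfig,
    n_reps: int = 100,
    models: tuple[str, ...] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    n_jobs: int = 1,
) -> ExperimentResult:
    """Repeatedly generate independent train/test cohorts and run the menu.

    Each replicate draws a fresh training and a fresh test dataset of the
    same size and with the same distribution parameters, from per-replicate
    substreams of the master seed. Replicate failures are logged and
    recorded as missing; more than 20% failures abort the run.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    models = tuple(models) if models is not None else MODEL_MENU
    seeds = _replicate_seeds(seed, n_reps)

    def one(r: int):
        s_train, s_test, s_fit = seeds[r]
        try:
            train = generate_dataset(replace(config, seed=s_train))
            test = generate_dataset(replace(config, seed=s_test))
            return _run_replicate(train, test, models, s_fit, r, n_folds)
        except Exception:
            logger.exception("replicate %d failed", r)
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(n_reps))
    else:
        results = [one(r) for r in range(n_reps)]
    return _collect(results, n_reps)


def run_real_data_experiment(
    data_file,
    n_splits: int = 100,
    models: tuple[str, ...] | None = None,
    seed: int = 0,
    train_fraction: float = 0.632,
    n_folds: int = 10,
    n_jobs: int = 1,
) -> ExperimentResult:
    """Same loop on a fixed cohort, with repeated stratified 0.632 splits."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    data = SubgroupedSurvivalData.from_csv(data_file)
    models = tuple(models) if models is not None else MODEL_MENU
    seeds = _replicate_seeds(seed, n_splits)

    def one(r: int):
        s_split, _, s_fit = seeds[r]
        try:
            train, test = stratified_split(data, train_fraction, seed=s_split)
            return _run_replicate(train, test, models, s_fit, r, n_folds)
        except Exception:
            logger.exception("split %d failed", r)
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(n_splits))
    else:
        results = [one(r) for r in range(n_splits)]
    return _collect(results, n_splits)
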