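"""Classification-based estimation of individual subgroup weights.

The weight of patient i in the model for subgroup s is the density ratio

    w_s(y, x) = p(y, x | s) / p(y, x) = p(s | y, x) / p(s),

i.e. the posterior probability of membership in s given covariates and
response, divided by the subgroup's prior (its relative frequency). The
posterior is treated as a multi-class classification problem on the
training data, with the covariates augmented by the survival response
(log observed time and event indicator), and is estimated out-of-fold by
k-fold cross-validation to prevent overfitting. Three classifiers are
supported: multinomial logistic regression with lasso or ridge penalty
(each tuning its own penalty by internal cross-validation) and a
500-tree random forest.

The resulting ratios are not constrained to (0, 1) — patients who clearly
belong to a small subgroup can receive large weights — and are passed to
the Cox fitter unmodified; the fitter normalizes them to sum to the sample
size, which leaves the estimate invariant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data import SubgroupedSurvivalData

__all__ = [
    "WeightMatrix",
    "estimate_subgroup_probs",
    "compute_weight_matrix",
    "estimate_weight_matrix",
    "group_separation_auc",
    "binary_auc",
    "assign_subgroup_folds",
    "write_weight_matrix",
    "read_weight_matrix",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("lasso", "ridge", "rf")


@dataclass(frozen=True)
class WeightMatrix:
    """Per-patient, per-subgroup weights plus their ingredients.

    ``values[i, s-1] = prob_matrix[i, s-1] / priors[s-1]``; entries may
    exceed 1.
    """

    values: np.ndarray
    prob_matrix: np.ndarray
    priors: np.ndarray
    classifier: str | None = None

    def column(self, subgroup: int) -> np.ndarray:
        """Weight vector for the model targeting ``subgroup`` (1-based)."""
        return self.values[:, subgroup - 1]


def _make_classifier(name: str, seed: int):
    if name == "lasso":
        clf = LogisticRegressionCV(
            Cs=8,
            cv=10,
            l1_ratios=(1,),
            solver="saga",
            max_iter=5000,
            tol=1e-3,
            random_state=seed,
            scoring="neg_log_loss",
            use_legacy_attributes=False,
            n_jobs=1,
        )
        return make_pipeline(StandardScaler(), clf)
    if name == "ridge":
        clf = LogisticRegressionCV(
            Cs=8,
            cv=10,
            l1_ratios=(0,),
            solver="lbfgs",
            max_iter=2000,
            scoring="neg_log_loss",
            use_legacy_attributes=False,
            n_jobs=1,
        )
        return make_pipeline(StandardScaler(), clf)
    if name == "rf":
        # 500 trees and a minimum node size of 10 mirror ranger's
        # probability-forest defaults
        return RandomForestClassifier(
            n_estimators=500, min_samples_leaf=10, random_state=seed, n_jobs=1
        )
    raise ValueError(f"classifier must be one of {CLASSIFIERS}, got {name!r}")


def assign_subgroup_folds(
    subgroups: np.ndarray, n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Subgroup-stratified fold ids; retries once if a training part loses a label."""
    labels = np.asarray(subgroups)
    all_labels = np.unique(labels)
    for attempt, s in enumerate((seed, seed + 1)):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=s % (2**31))
        fold_of = np.empty(labels.shape[0], dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
            fold_of[test_idx] = f
        ok = all(
            np.array_equal(np.unique(labels[fold_of != f]), all_labels)
            for f in range(n_folds)
        )
        if ok:
            if attempt:
                logger.warning("refolded with a new seed after a degenerate partition")
            return fold_of
    raise ValueError(
        "could not build folds whose training parts contain every subgroup; "
        "reduce n_folds or enlarge the smallest subgroup"
    )


def estimate_subgroup_probs(
    data: SubgroupedSurvivalData,
    classifier: str = "rf",
    n_folds: int = 10,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Out-of-fold posterior probabilities p(s | y, x), one column per subgroup.

    The classifier features are the covariates augmented by log(t) and the
    event indicator. Entry (i, s) comes from the fold model that did not see
    patient i; rows sum to 1.
    """
    s_count = data.n_subgroups
    if s_count < 2:
        raise ValueError("need at least two subgroups to classify")
    features = np.column_stack(
        [data.covariates, np.log(data.times), data.events.astype(float)]
    )
    if fold_ids is None:
        fold_ids = assign_subgroup_folds(data.subgroups, n_folds, seed)
    else:
        fold_ids = np.asarray(fold_ids)
        if fold_ids.shape[0] != data.n:
            raise ValueError("fold_ids must have length n")
    probs = np.zeros((data.n, s_count))
    for f in np.unique(fold_ids):
        test = fold_ids == f
        train = ~test
        train_labels = data.subgroups[train]
        if np.unique(train_labels).shape[0] != s_count:
            raise ValueError(f"training part of fold {f} is missing a subgroup label")
        clf = _make_classifier(classifier, seed=int((seed * 1009 + int(f) + 1) % (2**31)))
        try:
            clf.fit(features[train], train_labels)
            p = clf.predict_proba(features[test])
        except Exception as exc:  # surface classifier diagnostics
            raise RuntimeError(
                f"classifier {classifier!r} failed on fold {f}: {exc}"
            ) from exc
        classes = clf[-1].classes_ if hasattr(clf, "steps") else clf.classes_
        for col, label in enumerate(classes):
            probs[test, int(label) - 1] = p[:, col]
    return probs


def compute_weight_matrix(
    prob_matrix: np.ndarray,
    subgroups: np.ndarray,
    classifier: str | None = None,
) -> WeightMatrix:
    """Scale posterior probabilities by inverse empirical priors."""
    prob = np.asarray(prob_matrix, dtype=float)
    labels = np.asarray(subgroups).astype(int)
    if prob.ndim != 2 or prob.shape[0] != labels.shape[0]:
        raise ValueError("prob_matrix must be n x S with one row per patient")
    if np.any(prob < 0) or not np.allclose(prob.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of prob_matrix must be probability vectors")
    s_count = prob.shape[1]
    counts = np.bincount(labels, minlength=s_count + 1)[1 : s_count + 1]
    if np.any(counts == 0):
        empty = (np.flatnonzero(counts == 0) + 1).tolist()
        raise ValueError(f"empty subgroup(s) {empty}: p(s) > 0 is required")
    priors = counts / labels.shape[0]
    return WeightMatrix(
        values=prob / priors[None, :],
        prob_matrix=prob,
        priors=priors,
        classifier=classifier,
    )


def estimate_weight_matrix(
    data: SubgroupedSurvivalData,
    classifier: str = "rf",
    n_folds: int = 10,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
) -> WeightMatrix:
    """Convenience wrapper: out-of-fold probabilities -> weight matrix."""
    probs = estimate_subgroup_probs(data, classifier, n_folds, seed, fold_ids)
    return compute_weight_matrix(probs, data.subgroups, classifier=classifier)


def binary_auc(is_positive: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC of a score for a binary membership vector."""
    y = np.asarray(is_positive).astype(int)
    if np.unique(y).shape[0] < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def group_separation_auc(
    data: SubgroupedSurvivalData,
    group_map: dict[int, int],
    classifier: str = "rf",
    seed: int = 0,
    n_folds: int = 10,
    prob_matrix: np.ndarray | None = None,
) -> float:
    """AUC for discriminating latent group 1 from group 2.

    The discrimination score of a patient is the sum of their out-of-fold
    subgroup probabilities over the subgroups mapped to group 1.
    """
    groups = np.array([group_map[int(s)] for s in data.subgroups])
    if np.unique(groups).shape[0] < 2:
        raise ValueError("group_map must assign both groups")
    if prob_matrix is None:
        prob_matrix = estimate_subgroup_probs(data, classifier, n_folds, seed)
    group1_cols = [s - 1 for s, g in group_map.items() if g == 1]
    scores = prob_matrix[:, group1_cols].sum(axis=1)
    return binary_auc(groups == 1, scores)


def write_weight_matrix(wm: WeightMatrix, csv_path, json_path=None, seed=None) -> None:
    cols = {f"subgroup_{s + 1}": wm.values[:, s] for s in range(wm.values.shape[1])}
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "classifier": wm.classifier,
            "priors": wm.priors.tolist(),
            "seed": seed,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_weight_matrix(csv_path) -> np.ndarray:
    return pd.read_csv(csv_path).to_numpy(dtype=float)
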