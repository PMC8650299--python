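"""Harrell's concordance index for risk-scored test sets.

Implements the classical (unweighted) C-index: the fraction of usable
patient pairs whose risk-score ordering agrees with their survival-time
ordering. A pair (i, i*) is usable iff patient i has an observed event
(delta_i = 1) and t_{i*} > t_i strictly; pairs where both patients die at
the same time, both are censored, or one is censored before the other dies
are excluded. Risk-score ties contribute 1/2. No inverse-probability-of-
censoring weighting and no truncation horizon are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SubgroupedSurvivalData

__all__ = ["RiskScoredTestSet", "harrell_c_index", "score_fit"]


@dataclass(frozen=True)
class RiskScoredTestSet:
    """Observed times/events plus linear risk scores r(x_i) = beta' x_i."""

    times: np.ndarray
    events: np.ndarray
    risk_scores: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        events = np.asarray(self.events).ravel().astype(int)
        scores = np.asarray(self.risk_scores, dtype=float).ravel()
        if not (times.shape == events.shape == scores.shape):
            raise ValueError("times, events and risk_scores must share length")
        if not np.all(np.isfinite(scores)):
            raise ValueError("risk scores must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "risk_scores", scores)


def harrell_c_index(testset: RiskScoredTestSet) -> float:
    """Concordance of risk scores with survival ordering over usable pairs.

    Returns ``(1/n_c) * sum_{i: delta_i=1} sum_{i*: t_{i*} > t_i}
    [1(r_{i*} < r_i) + 1/2 * 1(r_{i*} = r_i)]`` with ``n_c`` the number of
    usable pairs. Raises ``ValueError`` when no pair is usable (the index is
    undefined then, not 0.5).
    """
    t = testset.times
    d = testset.events
    r = testset.risk_scores
    usable = (d[:, None] == 1) & (t[None, :] > t[:, None])
    n_c = int(usable.sum())
    if n_c == 0:
        raise ValueError("no usable pairs; the C-index is undefined")
    concordant = (r[None, :] < r[:, None]).astype(float)
    concordant += 0.5 * (r[None, :] == r[:, None])
    return float((usable * concordant).sum() / n_c)


def score_fit(fit, test: SubgroupedSurvivalData, target_subgroup: int) -> float:
    """C-index of a fitted model on one subgroup's test rows.

    Risk scores are ``beta_hat' x`` on the test covariates; for a combined-
    mode fit the subgroup-indicator dummy columns are reconstructed from the
    test labels with the training reference level.
    """
    mask = test.subgroups == target_subgroup
    if not mask.any():
        raise ValueError(f"subgroup {target_subgroup} absent from test data")
    x = test.covariates[mask]
    dummy_levels = getattr(fit, "dummy_levels", None)
    if dummy_levels:
        labels = test.subgroups[mask]
        dummies = np.column_stack(
            [(labels == lev).astype(float) for lev in dummy_levels]
        )
        x = np.hstack([x, dummies])
    beta = np.asarray(fit.coefficients, dtype=float)
    if beta.shape[0] != x.shape[1]:
        raise ValueError(
            f"fit has {beta.shape[0]} coefficients but test rows have {x.shape[1]} columns"
        )
    scores = x @ beta
    return harrell_c_index(
        RiskScoredTestSet(test.times[mask], test.events[mask], scores)
    )
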