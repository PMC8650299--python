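"""Shared survival-data container and delimited-text I/O.

Every module in the package consumes :class:`SubgroupedSurvivalData`: aligned
arrays of observed times, event indicators, integer subgroup labels and a
numeric covariate matrix. The on-disk dialect is a delimited text file with
mandatory named columns ``time``, ``status``, ``subgroup``; every remaining
column is treated as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time", "status", "subgroup")


@dataclass(frozen=True)
class SubgroupedSurvivalData:
    """Right-censored survival data with known patient subgroups.

    Parameters
    ----------
    times : array of shape (n,)
        Observed times ``t_i = min(T_i, C_i)``, strictly positive.
    events : array of shape (n,)
        Event indicators ``delta_i`` (1 = event observed, 0 = censored).
    subgroups : array of shape (n,)
        Integer subgroup labels in ``1..S``; every label must occur.
    covariates : array of shape (n, p)
        Numeric covariate matrix (e.g. gene-expression values).
    covariate_names : tuple of str, optional
        Column names; defaults to ``x1..xp``.
    """

    times: np.ndarray
    events: np.ndarray
    subgroups: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        events = np.asarray(self.events).ravel()
        subgroups = np.asarray(self.subgroups).ravel()
        covariates = np.asarray(self.covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates.reshape(-1, 1)
        if covariates.ndim != 2:
            raise ValueError("covariates must be a 2-d matrix")
        n = times.shape[0]
        if events.shape[0] != n or subgroups.shape[0] != n or covariates.shape[0] != n:
            raise ValueError(
                "times, events, subgroups and covariates must share length n "
                f"(got {n}, {events.shape[0]}, {subgroups.shape[0]}, {covariates.shape[0]})"
            )
        if n > 0:
            if not np.all(np.isfinite(times)) or np.any(times <= 0):
                raise ValueError("times must be finite and strictly positive")
            if not np.isin(events, (0, 1)).all():
                raise ValueError("events must be binary 0/1")
            if not np.all(np.isfinite(covariates)):
                raise ValueError("covariates must be finite (no missing values)")
            subgroups = subgroups.astype(int)
            if np.any(subgroups < 1):
                raise ValueError("subgroup labels must be integers >= 1")
            s_max = int(subgroups.max())
            present = np.unique(subgroups)
            if present.shape[0] != s_max:
                missing = sorted(set(range(1, s_max + 1)) - set(present.tolist()))
                raise ValueError(f"every label in 1..S must occur; missing {missing}")
        else:
            subgroups = subgroups.astype(int)
        names = self.covariate_names
        if names is None:
            names = tuple(f"x{j + 1}" for j in range(covariates.shape[1]))
        else:
            names = tuple(str(c) for c in names)
            if len(names) != covariates.shape[1]:
                raise ValueError("covariate_names length must equal p")
        events = events.astype(int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "subgroups", subgroups)
        object.__setattr__(self, "covariates", covariates)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_subgroups(self) -> int:
        return int(self.subgroups.max()) if self.n else 0

    def subset(self, indices, relabel: bool = False) -> "SubgroupedSurvivalData":
        """Row subset; ``relabel=True`` remaps the surviving labels to 1..S'."""
        indices = np.asarray(indices)
        sub = self.subgroups[indices]
        if relabel and sub.size:
            _, sub = np.unique(sub, return_inverse=True)
            sub = sub + 1
        return SubgroupedSurvivalData(
            times=self.times[indices],
            events=self.events[indices],
            subgroups=sub,
            covariates=self.covariates[indices],
            covariate_names=self.covariate_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "status": self.events, "subgroup": self.subgroups}
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    def to_csv(self, path) -> None:
        sep = "\t" if str(path).endswith(".tsv") else ","
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubgroupedSurvivalData":
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing")
        cov_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
        return cls(
            times=df["time"].to_numpy(dtype=float),
            events=df["status"].to_numpy(),
            subgroups=df["subgroup"].to_numpy(),
            covariates=df[cov_cols].to_numpy(dtype=float),
            covariate_names=tuple(cov_cols),
        )

    @classmethod
    def from_csv(cls, path) -> "SubgroupedSurvivalData":
        sep = "\t" if str(path).endswith(".tsv") else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))
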