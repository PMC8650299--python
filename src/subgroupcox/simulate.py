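"""Synthetic survival cohorts with latent-group structure.

The generator emulates a multicenter gene-expression study: four equally
sized subgroups (1A, 1B, 2A, 2B) drawn from two latent groups. Groups differ
in their effect vectors on the hazard and — controlled by a similarity dial
``epsilon`` in [0, 1] — in the mean expression of prognostic genes. Event and
censoring times both follow group-specific Weibull distributions via the
inverse-transform construction

    T = (-log U / (eta * exp(x' beta)))**(1 / kappa),   U ~ U[0, 1],

so censoring is non-informative and, because the censoring time shares the
event time's full distribution (same eta, kappa, linear predictor, independent
uniform), every patient has exactly a 50% chance of being censored.

Baseline Weibull parameters are anchored to 3- and 5-year Kaplan-Meier
survival fractions of two real lung-cancer cohorts: (57%, 42%) for group 1
and (75%, 62%) for group 2.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import SubgroupedSurvivalData

__all__ = [
    "EffectTable",
    "WeibullParams",
    "SimulationConfig",
    "solve_weibull_params",
    "covariate_means",
    "simulate_group",
    "generate_dataset",
    "parameter_grid",
    "EFFECTS_GROUP1",
    "EFFECTS_GROUP2",
    "COHORT1_ANCHORS",
    "COHORT2_ANCHORS",
]

# Effects of the first 12 genes: subgroup-specific (1-4), opposite (5-6),
# same direction but different size (7-8), joint (9-12). They sum to zero
# within each group, keeping the simulated survival times on a sane scale.
EFFECTS_GROUP1 = np.array(
    [1.0, 1.0, 0.0, 0.0, -0.5, 0.5, 0.75, 0.25, -1.0, -1.0, -0.75, -0.25]
)
EFFECTS_GROUP2 = np.array(
    [0.0, 0.0, 1.0, 1.0, 0.5, -0.5, 0.25, 0.75, -1.0, -1.0, -0.75, -0.25]
)

# (3-year, 5-year) Kaplan-Meier survival anchors of the two reference cohorts.
COHORT1_ANCHORS = (0.57, 0.42)
COHORT2_ANCHORS = (0.75, 0.62)

_ALLOWED_MAGNITUDES = (0.0, 0.25, 0.5, 0.75, 1.0)

# Simulation-study grid: n per subgroup x number of genes x similarity dial.
GRID_N = (20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 500, 1000)
GRID_P = (12, 100, 200)
GRID_EPSILON = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass(frozen=True)
class EffectTable:
    """Per-group true log-hazard effect vectors (length p each)."""

    beta1: np.ndarray
    beta2: np.ndarray

    def __post_init__(self) -> None:
        b1 = np.asarray(self.beta1, dtype=float).ravel()
        b2 = np.asarray(self.beta2, dtype=float).ravel()
        if b1.shape != b2.shape:
            raise ValueError("beta1 and beta2 must have equal length")
        object.__setattr__(self, "beta1", b1)
        object.__setattr__(self, "beta2", b2)

    @property
    def p(self) -> int:
        return self.beta1.shape[0]

    def for_group(self, group: int) -> np.ndarray:
        if group == 1:
            return self.beta1
        if group == 2:
            return self.beta2
        raise ValueError("group must be 1 or 2")

    @classmethod
    def default(cls, p: int) -> "EffectTable":
        """Canonical 12-gene table padded with zeros up to p covariates."""
        if p < 12:
            raise ValueError("the canonical effect table requires p >= 12")
        pad = np.zeros(p - 12)
        return cls(
            beta1=np.concatenate([EFFECTS_GROUP1, pad]),
            beta2=np.concatenate([EFFECTS_GROUP2, pad]),
        )


@dataclass(frozen=True)
class WeibullParams:
    """Weibull baseline hazard with survival S(t) = exp(-eta * t**kappa)."""

    eta: float
    kappa: float

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.kappa > 0):
            raise ValueError("eta and kappa must be positive")

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.eta * np.asarray(t, dtype=float) ** self.kappa)


def solve_weibull_params(
    surv_t1: float, surv_t2: float, t1: float = 3.0, t2: float = 5.0
) -> WeibullParams:
    """Solve (eta, kappa) from two baseline survival anchors.

    The system ``exp(-eta * t1**kappa) = surv_t1``, ``exp(-eta * t2**kappa) =
    surv_t2`` has the closed-form solution

        kappa = log(log(surv_t1) / log(surv_t2)) / log(t1 / t2)
        eta   = -log(surv_t1) / t1**kappa
    """
    if not (0.0 < surv_t2 < surv_t1 < 1.0):
        raise ValueError("anchors must satisfy 0 < surv_t2 < surv_t1 < 1")
    if not (0.0 < t1 < t2):
        raise ValueError("anchor times must satisfy 0 < t1 < t2")
    kappa = math.log(math.log(surv_t1) / math.log(surv_t2)) / math.log(t1 / t2)
    eta = -math.log(surv_t1) / t1**kappa
    return WeibullParams(eta=eta, kappa=kappa)


def _default_weibull() -> tuple[WeibullParams, WeibullParams]:
    return (
        solve_weibull_params(*COHORT1_ANCHORS),
        solve_weibull_params(*COHORT2_ANCHORS),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic scenario.

    ``n_per_subgroup``, ``p`` and ``epsilon`` span the study grid; effect
    vectors and Weibull baselines default to the canonical table and the
    cohort-anchored parameters.
    """

    n_per_subgroup: int
    p: int
    epsilon: float
    seed: int = 0
    effects: EffectTable | None = None
    weibull: tuple[WeibullParams, WeibullParams] | None = None

    def __post_init__(self) -> None:
        if self.n_per_subgroup < 1:
            raise ValueError("n_per_subgroup must be >= 1")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        effects = self.effects
        if effects is None:
            effects = EffectTable.default(self.p)
        if effects.p != self.p:
            raise ValueError("effect vectors must have length p")
        weibull = self.weibull
        if weibull is None:
            weibull = _default_weibull()
        object.__setattr__(self, "effects", effects)
        object.__setattr__(self, "weibull", tuple(weibull))

    def to_json(self, path=None) -> str:
        payload = {
            "n_per_subgroup": self.n_per_subgroup,
            "p": self.p,
            "epsilon": self.epsilon,
            "seed": self.seed,
            "effects": {
                "beta1": self.effects.beta1.tolist(),
                "beta2": self.effects.beta2.tolist(),
            },
            "weibull": [
                {"eta": w.eta, "kappa": w.kappa} for w in self.weibull
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        effects = payload.get("effects")
        if effects is not None:
            effects = EffectTable(np.asarray(effects["beta1"]), np.asarray(effects["beta2"]))
        weibull = payload.get("weibull")
        if weibull is not None:
            weibull = tuple(WeibullParams(w["eta"], w["kappa"]) for w in weibull)
        return cls(
            n_per_subgroup=int(payload["n_per_subgroup"]),
            p=int(payload["p"]),
            epsilon=float(payload["epsilon"]),
            seed=int(payload.get("seed", 0)),
            effects=effects,
            weibull=weibull,
        )


def covariate_means(effects_for_group: np.ndarray, epsilon: float) -> np.ndarray:
    """Map a group's effect vector to gene-expression means.

    Genes with a strong effect (|beta| = 1) get mean ``4 + 4*epsilon``,
    moderate effects (|beta| in {0.5, 0.75}) get ``4 + 2*epsilon``, weak or
    absent effects (|beta| in {0, 0.25}) stay at the baseline mean 4. The
    magnitudes mimic log2-scale expression values, where prognostic genes are
    assumed to be expressed above the noise floor.
    """
    beta = np.asarray(effects_for_group, dtype=float).ravel()
    mag = np.abs(beta)
    ok = np.isclose(mag[:, None], np.asarray(_ALLOWED_MAGNITUDES)[None, :]).any(axis=1)
    if not ok.all():
        bad = np.unique(mag[~ok])
        raise ValueError(f"effect magnitudes must be in {_ALLOWED_MAGNITUDES}; got {bad}")
    mu = np.full(beta.shape, 4.0)
    mu[np.isclose(mag, 1.0)] += 4.0 * epsilon
    mu[np.isclose(mag, 0.5) | np.isclose(mag, 0.75)] += 2.0 * epsilon
    return mu


def simulate_group(
    n: int,
    p: int,
    group: int,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Draw one group's covariates, observed times and event indicators.

    Covariates are i.i.d. normal with the group's mean vector and identity
    covariance. Event and censoring times use the same inverse-transform
    mechanism with independent uniforms, so ``P(delta = 1) = 1/2`` exactly.

    Returns ``(times, events, covariates)`` arrays of length n.
    """
    beta = config.effects.for_group(group)[:p]
    wb = config.weibull[group - 1]
    mu = covariate_means(beta, config.epsilon)
    x = rng.standard_normal((n, p)) + mu[None, :]
    lp = x @ beta
    scale = wb.eta * np.exp(lp)
    u_event = rng.uniform(size=n)
    u_cens = rng.uniform(size=n)
    t_event = (-np.log(u_event) / scale) ** (1.0 / wb.kappa)
    t_cens = (-np.log(u_cens) / scale) ** (1.0 / wb.kappa)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events, x


def generate_dataset(config: SimulationConfig) -> SubgroupedSurvivalData:
    """Generate the four-subgroup cohort (labels 1..4; groups 1|1|2|2)."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_per_subgroup, config.p
    times, events, covs, labels = [], [], [], []
    for label, group in ((1, 1), (2, 1), (3, 2), (4, 2)):
        t, d, x = simulate_group(n, p, group, config, rng)
        times.append(t)
        events.append(d)
        covs.append(x)
        labels.append(np.full(n, label))
    return SubgroupedSurvivalData(
        times=np.concatenate(times),
        events=np.concatenate(events),
        subgroups=np.concatenate(labels),
        covariates=np.vstack(covs),
        covariate_names=tuple(f"gene{j + 1}" for j in range(p)),
    )


def parameter_grid() -> list[dict]:
    """Enumerate the full simulation-study grid (252 scenarios)."""
    return [
        {"n_per_subgroup": n, "p": p, "epsilon": eps}
        for n, p, eps in itertools.product(GRID_N, GRID_P, GRID_EPSILON)
    ]


def replace_config(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """dataclasses.replace that tolerates the derived default fields."""
    return replace(config, **kwargs)
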