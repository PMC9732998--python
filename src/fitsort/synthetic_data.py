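"""Synthetic hospital-like sorting problems and a consistent simulated DM.

The generator emulates the statistical shape of a hospital consequence matrix:
right-skewed positive unit costs (log-normal), heavy-tailed monthly demand
counts (negative binomial), small-integer lead times, an ordinal 1-3
criticality rating, and storage volumes spanning a couple of orders of
magnitude (log-uniform).  It deliberately does *not* model correlations
between criteria or real procurement dynamics — it exists so that every stage
of the pipeline (normalization, LP bounds, elicitation, assignment) can be
exercised end-to-end against a known ground truth.

The :class:`SimulatedDM` holds a hidden, strictly decreasing weight vector
``k*`` (indexed by ranking position) and answers tradeoff questions exactly
as an additive-model decision maker with those weights would, up to an
optional indifference tolerance.  Since its answers are consistent by
construction, elicitation run against it must keep the true weights inside
the weight space and the true class inside every viable set — the central
recovery property the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elicitation import Answer, ElicitationQuestion
from .problem_model import (
    ClassProfile,
    ConsequenceMatrix,
    Criterion,
    ValueMatrix,
)

__all__ = [
    "SyntheticConfig",
    "SimulatedDM",
    "generate_problem",
    "simulate_dm_answer",
    "true_global_values",
    "true_classification",
]

#: importance order used for synthetic problems (most important first),
#: matching the hospital case: demand > criticality > lead time > cost > volume
DEFAULT_RANKING = ("demand", "criticality", "lead_time", "cost", "volume")


@dataclass(frozen=True)
class SyntheticConfig:
    """Distribution parameters for a hospital-like consequence matrix.

    Defaults mimic the spreads of the bundled 48-item dataset: costs from
    cents to thousands of BRL, demands from a handful to tens of thousands of
    units/month, lead times of 2-60 days, mostly medium/high criticality,
    volumes over ~2.5 orders of magnitude.
    """

    n_alternatives: int = 48
    seed: int = 0
    cost_log_mu: float = 3.0
    cost_log_sigma: float = 1.8
    demand_dispersion: float = 0.45  # negative-binomial n (small => heavy tail)
    demand_mean: float = 900.0
    lead_time_range: tuple[int, int] = (2, 60)
    criticality_probs: tuple[float, float, float] = (0.2, 0.4, 0.4)
    volume_range: tuple[float, float] = (1e-4, 7e-2)
    max_regen: int = 10  # retries for a degenerate (constant) column

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValueError("need at least 2 alternatives")
        probs = np.asarray(self.criticality_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("criticality_probs must be 3 nonnegative values summing to 1")
        lo, hi = self.lead_time_range
        if not (0 < lo < hi):
            raise ValueError("lead_time_range must be increasing positive integers")
        v_lo, v_hi = self.volume_range
        if not (0 < v_lo < v_hi):
            raise ValueError("volume_range must be increasing and positive")


def synthetic_criteria() -> tuple[Criterion, ...]:
    return (
        Criterion("cost", "minimize"),
        Criterion("demand", "maximize"),
        Criterion("lead_time", "minimize"),
        Criterion("criticality", "maximize", scale_kind="built",
                  worst_level=1, best_level=3),
        Criterion("volume", "minimize"),
    )


def generate_problem(config: SyntheticConfig) -> ConsequenceMatrix:
    """Seeded hospital-like consequence matrix with no constant columns.

    A column that comes out constant (possible for criticality with extreme
    probabilities, or tiny n) is redrawn up to ``config.max_regen`` times;
    if it stays constant a :class:`ValueError` is raised, because a constant
    criterion cannot be normalized without declared levels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_alternatives

    def draw_cost() -> np.ndarray:
        return np.round(rng.lognormal(config.cost_log_mu, config.cost_log_sigma, n), 2)

    def draw_demand() -> np.ndarray:
        r = config.demand_dispersion
        p = r / (r + config.demand_mean)
        return 1.0 + rng.negative_binomial(r, p, n).astype(float)

    def draw_lead() -> np.ndarray:
        lo, hi = config.lead_time_range
        return rng.integers(lo, hi + 1, n).astype(float)

    def draw_crit() -> np.ndarray:
        return rng.choice([1.0, 2.0, 3.0], size=n, p=config.criticality_probs)

    def draw_volume() -> np.ndarray:
        lo, hi = config.volume_range
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    drawers = {
        "cost": draw_cost,
        "demand": draw_demand,
        "lead_time": draw_lead,
        "criticality": draw_crit,
        "volume": draw_volume,
    }
    cols = {}
    for name, draw in drawers.items():
        col = draw()
        tries = 0
        while np.ptp(col) == 0.0:
            tries += 1
            if tries > config.max_regen:
                raise ValueError(
                    f"synthetic column {name!r} is constant after "
                    f"{config.max_regen} redraws; adjust the configuration"
                )
            col = draw()
        cols[name] = col
    index = [f"item_{i:03d}" for i in range(n)]
    df = pd.DataFrame(cols, index=pd.Index(index, name="alternative"))
    return ConsequenceMatrix(criteria=synthetic_criteria(), performance=df)


@dataclass(frozen=True)
class SimulatedDM:
    """A perfectly consistent additive-model decision maker.

    ``true_weights`` are indexed by *ranking position* (most important
    first), strictly decreasing, positive, summing to 1.  ``indifference_
    tolerance`` tau >= 0 widens the band of value differences reported as
    indifference; tau = 0 models a DM who always discriminates.
    """

    true_weights: tuple[float, ...]
    indifference_tolerance: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true weights must be positive and sum to 1")
        if (np.diff(w) >= 0).any():
            raise ValueError("true weights must be strictly decreasing")
        if self.indifference_tolerance < 0:
            raise ValueError("indifference tolerance must be >= 0")
        object.__setattr__(self, "true_weights", tuple(float(x) for x in w))

    @classmethod
    def random(
        cls,
        n: int,
        rng: np.random.Generator,
        tau: float = 0.0,
        min_gap: float = 1e-3,
    ) -> "SimulatedDM":
        """A random strictly decreasing weight vector (flat Dirichlet, sorted;
        redrawn until consecutive gaps exceed ``min_gap``)."""
        for _ in range(1000):
            w = np.sort(rng.dirichlet(np.ones(n)))[::-1]
            if (np.diff(w) < -min_gap).all():
                return cls(tuple(w), indifference_tolerance=tau)
        raise RuntimeError("could not draw strictly decreasing weights")


def simulate_dm_answer(dm: SimulatedDM, q: ElicitationQuestion) -> Answer:
    """Answer a tradeoff question from the hidden weights.

    Compares option A's worth ``level * k*_upper`` with option B's
    ``k*_lower``; differences within the indifference tolerance are reported
    as indifference.
    """
    d = q.level * dm.true_weights[q.upper] - dm.true_weights[q.lower]
    if abs(d) <= dm.indifference_tolerance:
        return Answer.INDIFFERENT
    return Answer.PREFER_A if d > 0 else Answer.PREFER_B


def true_global_values(
    values: ValueMatrix,
    dm: SimulatedDM,
    ranking: tuple[str, ...] | list[str] | None = None,
) -> pd.Series:
    """Global value of every alternative at the hidden weights.

    ``ranking`` maps ranking positions to criterion (column) names; by
    default the columns are assumed already ordered most-important-first.
    """
    cols = list(values.values.columns)
    order = list(ranking) if ranking is not None else cols
    if sorted(order) != sorted(cols):
        raise ValueError("ranking must be a permutation of the value columns")
    w = np.asarray(dm.true_weights)
    if w.shape != (len(cols),):
        raise ValueError(
            f"DM has {w.size} weights but the matrix has {len(cols)} criteria"
        )
    return values.values[order].to_numpy() @ w + pd.Series(
        0.0, index=values.values.index
    )


def true_classification(
    values: ValueMatrix,
    dm: SimulatedDM,
    profile: ClassProfile,
    ranking: tuple[str, ...] | list[str] | None = None,
) -> pd.Series:
    """Each alternative's single true class at the hidden weights."""
    g = true_global_values(values, dm, ranking)
    return g.map(profile.band_label)
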