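"""LP bounds on each alternative's global value, and assignment to classes.

For every alternative ``a`` with marginal-value vector ``v`` two linear
programs are solved over the current weight space: ``s1 = min_k sum k_i v_i``
and ``s2 = max_k sum k_i v_i``.  The closed interval ``[s1, s2]`` is then
intersected with the class bands of the profile: every band touched is a
*viable* class.  If the interval fits inside one band the alternative is
singly classified; otherwise the recommendation rule picks the most preferred
(most critical) viable class, the conservative choice for monitoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .problem_model import ClassProfile, ValueMatrix
from .weight_space import InfeasibleWeightSpaceError, WeightSpace

__all__ = [
    "ClassificationResult",
    "Classification",
    "ClassificationSummary",
    "solve_bounds",
    "assign_classes",
    "recommend_class",
    "classify_all",
    "classify_from_bounds",
    "count_summary",
]

#: slack applied before comparing a bound with a band threshold, so that
#: solver noise of order 1e-12 cannot flip an exact-threshold value across
#: a band boundary
BAND_TOL = 1e-9


@dataclass(frozen=True)
class ClassificationResult:
    """Per-alternative outcome: LP bounds, viable classes, recommendation.

    ``viable_classes`` is ordered most preferred first (e.g. ``("B", "M")``),
    matching how multi-class assignments are conventionally reported.
    """

    alternative: str
    s1: float
    s2: float
    viable_classes: tuple[str, ...]
    recommended: str

    @property
    def is_single(self) -> bool:
        return len(self.viable_classes) == 1


@dataclass(frozen=True)
class Classification:
    """Results for a whole matrix plus the headline count."""

    results: tuple[ClassificationResult, ...]
    n_singly_classified: int

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Report table: alternative, s1, s2, viable classes ("|"), recommended."""
        return pd.DataFrame(
            {
                "alternative": [r.alternative for r in self.results],
                "s1": [r.s1 for r in self.results],
                "s2": [r.s2 for r in self.results],
                "viable_classes": ["|".join(r.viable_classes) for r in self.results],
                "recommended": [r.recommended for r in self.results],
            }
        ).set_index("alternative")


def solve_bounds(
    values: Sequence[float], space: WeightSpace
) -> tuple[float, float]:
    """Min and max global value of one alternative over the weight space.

    Parameters
    ----------
    values
        The alternative's marginal-value vector, original criterion order,
        entries in [0, 1].
    space
        Current weight space; must be feasible.

    Returns
    -------
    (s1, s2)
        Clipped to [0, 1] to absorb solver round-off.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (space.n,):
        raise ValueError(f"expected {space.n} marginal values, got {v.shape}")
    if ((v < -1e-9) | (v > 1 + 1e-9)).any():
        raise ValueError("marginal values must lie in [0, 1]")
    A_ub, b_ub, A_eq, b_eq = space.linear_system()
    kwargs = dict(A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0.0, 1.0), method="highs")
    lo = linprog(v, **kwargs)
    hi = linprog(-v, **kwargs)
    if not (lo.success and hi.success):
        raise InfeasibleWeightSpaceError(
            "weight space is empty; retract the latest constraint"
        )
    s1 = float(np.clip(lo.fun, 0.0, 1.0))
    s2 = float(np.clip(-hi.fun, 0.0, 1.0))
    if s1 > s2:  # pure round-off; the polytope is nonempty
        s1 = s2 = 0.5 * (s1 + s2)
    return s1, s2


def assign_classes(
    s1: float, s2: float, profile: ClassProfile, tol: float = BAND_TOL
) -> tuple[str, ...]:
    """All classes whose band intersects the closed interval ``[s1, s2]``.

    Returned most preferred first.  Singleton iff both bounds fall in the
    same band; an interval straddling several thresholds yields every band in
    between (three-class spans are possible in principle).
    """
    if not (-tol <= s1 <= s2 + tol and s2 <= 1 + tol):
        raise ValueError(f"need 0 <= s1 <= s2 <= 1, got ({s1}, {s2})")
    lo = profile.band_index(s1, tol)
    hi = profile.band_index(s2, tol)
    return tuple(profile.labels[r] for r in range(hi, lo - 1, -1))


def recommend_class(viable: Iterable[str], profile: ClassProfile) -> str:
    """The most preferred (most critical) label among the viable classes."""
    viable = list(viable)
    if not viable:
        raise ValueError("viable class set must be nonempty")
    return max(viable, key=profile.preference_rank)


def classify_all(
    values: ValueMatrix, space: WeightSpace, profile: ClassProfile
) -> Classification:
    """Solve both LPs for every alternative and assign viable classes."""
    results = []
    for alt in values.alternatives:
        s1, s2 = solve_bounds(values.row(alt), space)
        viable = assign_classes(s1, s2, profile)
        results.append(
            ClassificationResult(
                alternative=alt,
                s1=s1,
                s2=s2,
                viable_classes=viable,
                recommended=recommend_class(viable, profile),
            )
        )
    n_single = sum(r.is_single for r in results)
    return Classification(results=tuple(results), n_singly_classified=n_single)


def classify_from_bounds(
    bounds: pd.DataFrame, profile: ClassProfile
) -> Classification:
    """Assign classes from precomputed (s1, s2) pairs, skipping the LPs.

    ``bounds`` is indexed by alternative with columns ``s1`` and ``s2`` —
    e.g. the bundled published bounds, or a report produced by an earlier
    run.  Thresholds do not enter the LPs, so reassignment under a different
    profile is exact.
    """
    results = []
    for alt, row in bounds.iterrows():
        s1, s2 = float(row["s1"]), float(row["s2"])
        viable = assign_classes(s1, s2, profile)
        results.append(
            ClassificationResult(
                alternative=str(alt),
                s1=s1,
                s2=s2,
                viable_classes=viable,
                recommended=recommend_class(viable, profile),
            )
        )
    n_single = sum(r.is_single for r in results)
    return Classification(results=tuple(results), n_singly_classified=n_single)


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts synthesizing a classification run.

    ``involvement`` counts, per class label, the alternatives whose viable
    set includes that label (multi-class alternatives count toward each of
    their classes); ``recommended`` counts by the recommendation rule.
    """

    n_alternatives: int
    n_single: int
    n_multi: int
    involvement: dict[str, int]
    recommended: dict[str, int]
    top_class_alternatives: tuple[str, ...]


def count_summary(
    results: Iterable[ClassificationResult],
    profile: ClassProfile | None = None,
) -> ClassificationSummary:
    """Aggregate counts for reporting (per-class involvement, singles, etc.)."""
    results = list(results)
    labels = profile.labels if profile is not None else tuple(
        sorted({lab for r in results for lab in r.viable_classes})
    )
    involvement = {lab: 0 for lab in labels}
    recommended: Counter = Counter({lab: 0 for lab in labels})
    for r in results:
        for lab in r.viable_classes:
            involvement[lab] += 1
        recommended[r.recommended] += 1
    top = labels[-1] if labels else None
    top_alts = tuple(
        r.alternative for r in results if top is not None and top in r.viable_classes
    )
    n_single = sum(r.is_single for r in results)
    return ClassificationSummary(
        n_alternatives=len(results),
        n_single=n_single,
        n_multi=len(results) - n_single,
        involvement=involvement,
        recommended=dict(recommended),
        top_class_alternatives=top_alts,
    )
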