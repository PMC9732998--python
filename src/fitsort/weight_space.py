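"""The space of criteria scaling constants, as a system of linear constraints.

Partial-information tradeoff elicitation never pins the weight vector ``k``
down to a point.  Instead it maintains a polytope: the weights sum to 1, are
nonnegative, respect the decision maker's importance ranking (with a small
strictness constant ``epsilon`` separating consecutive ranks), and satisfy one
linear inequality per answered tradeoff question.

A tradeoff question compares two hypothetical outcomes: criterion *i* (the
higher-ranked one) at a partial level whose marginal value is ``lambda``
versus criterion *j* at its best level.  The first option is worth
``lambda * k_i``, the second ``k_j``, for any weight vector, so

* preferring the first encodes  ``lambda * k_i >= k_j + epsilon``,
* preferring the second encodes ``lambda * k_i + epsilon <= k_j``,
* indifference encodes          ``lambda * k_i == k_j`` (no epsilon).

All feasibility and optimization questions about the polytope reduce to small
linear programs, solved with HiGHS via :func:`scipy.optimize.linprog`.  For
ordering-only spaces with ``epsilon = 0`` the polytope is the ordered simplex,
whose extreme points are known in closed form; :func:`enumerate_vertices`
exposes them as an exact oracle for testing the LP path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Relation",
    "TradeoffConstraint",
    "WeightSpace",
    "InfeasibleWeightSpaceError",
    "initial_weight_space",
    "add_constraint",
    "is_feasible",
    "enumerate_vertices",
    "weight_ranges",
    "max_epsilon",
]

Relation = Literal["prefer_upper", "prefer_lower", "indifferent"]

_RELATIONS = ("prefer_upper", "prefer_lower", "indifferent")


class InfeasibleWeightSpaceError(RuntimeError):
    """The constraint system admits no weight vector (inconsistent answers)."""


def max_epsilon(n: int) -> float:
    """Upper bound accepted for the strictness constant with ``n`` criteria.

    ``1 / (2 n^2)`` is comfortably below the largest epsilon for which the
    base ordering system stays feasible (``2 / (n (n - 1))``).
    """
    return 1.0 / (2.0 * n * n)


@dataclass(frozen=True)
class TradeoffConstraint:
    """One answered tradeoff question, as a linear constraint on the weights.

    ``upper`` and ``lower`` are *ranking positions* (0-based, ``upper <
    lower``), not raw criterion indices; ``level`` is the marginal value
    ``lambda`` of the probed outcome on the higher-ranked criterion.
    """

    upper: int
    lower: int
    level: float
    relation: Relation

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not (0 <= self.upper < self.lower):
            raise ValueError(
                f"need 0 <= upper < lower (ranking positions), got "
                f"({self.upper}, {self.lower})"
            )
        if not (0.0 < self.level < 1.0):
            # level 1 duplicates the ordering constraint; level 0 is vacuous
            raise ValueError(f"level must lie strictly in (0, 1), got {self.level}")


@dataclass(frozen=True)
class WeightSpace:
    """The polytope of admissible weight vectors.

    ``ranking`` is a permutation of criterion indices, most important first;
    weight vectors are always expressed in the *original* criterion order.
    Base constraints (always present): ``sum k = 1``, ``k >= 0`` and
    ``k[ranking[r]] >= k[ranking[r+1]] + epsilon``.
    """

    ranking: tuple[int, ...]
    epsilon: float = 1e-6
    constraints: tuple[TradeoffConstraint, ...] = ()

    def __post_init__(self) -> None:
        ranking = tuple(int(i) for i in self.ranking)
        object.__setattr__(self, "ranking", ranking)
        object.__setattr__(self, "constraints", tuple(self.constraints))
        n = len(ranking)
        if sorted(ranking) != list(range(n)):
            raise ValueError(f"ranking must be a permutation of 0..{n - 1}")
        if not (0.0 <= self.epsilon < max_epsilon(n)):
            raise ValueError(
                f"epsilon must satisfy 0 <= epsilon < 1/(2 n^2) = "
                f"{max_epsilon(n):.3g} for n = {n}, got {self.epsilon}"
            )
        for c in self.constraints:
            if c.lower >= n:
                raise ValueError(
                    f"constraint references ranking position {c.lower} but "
                    f"there are only {n} criteria"
                )

    @property
    def n(self) -> int:
        return len(self.ranking)

    def with_constraint(self, c: TradeoffConstraint) -> "WeightSpace":
        """A new space with ``c`` appended; self is untouched (undo = keep old)."""
        return WeightSpace(self.ranking, self.epsilon, self.constraints + (c,))

    def without_last_constraint(self) -> "WeightSpace":
        return WeightSpace(self.ranking, self.epsilon, self.constraints[:-1])

    def linear_system(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(A_ub, b_ub, A_eq, b_eq) with variables in original criterion order."""
        n = self.n
        rows: list[np.ndarray] = []
        rhs: list[float] = []

        def row(coeffs: dict[int, float], bound: float) -> None:
            r = np.zeros(n)
            for idx, val in coeffs.items():
                r[idx] += val
            rows.append(r)
            rhs.append(bound)

        for r in range(n - 1):
            hi, lo = self.ranking[r], self.ranking[r + 1]
            row({lo: 1.0, hi: -1.0}, -self.epsilon)  # k_lo - k_hi <= -eps
        for c in self.constraints:
            ci, cj = self.ranking[c.upper], self.ranking[c.lower]
            if c.relation == "prefer_upper":
                # lambda k_i >= k_j + eps
                row({cj: 1.0, ci: -c.level}, -self.epsilon)
            elif c.relation == "prefer_lower":
                # lambda k_i + eps <= k_j
                row({ci: c.level, cj: -1.0}, -self.epsilon)
            else:  # indifferent: lambda k_i == k_j
                row({ci: c.level, cj: -1.0}, 0.0)
                row({cj: 1.0, ci: -c.level}, 0.0)
        A_ub = np.vstack(rows) if rows else np.zeros((0, n))
        b_ub = np.asarray(rhs)
        A_eq = np.ones((1, n))
        b_eq = np.ones(1)
        return A_ub, b_ub, A_eq, b_eq


def initial_weight_space(
    ranking: Sequence[int], epsilon: float = 1e-6
) -> WeightSpace:
    """Weight space containing only the base (ordering) constraints."""
    return WeightSpace(ranking=tuple(ranking), epsilon=epsilon)


def add_constraint(space: WeightSpace, c: TradeoffConstraint) -> WeightSpace:
    """Non-destructively append a tradeoff constraint (see WeightSpace docs)."""
    return space.with_constraint(c)


def _solve(space: WeightSpace, c: np.ndarray):
    A_ub, b_ub, A_eq, b_eq = space.linear_system()
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0.0, 1.0),
        method="highs",
    )
    return res


def is_feasible(space: WeightSpace) -> bool:
    """Whether the full system admits a weight vector (zero-objective LP)."""
    return bool(_solve(space, np.zeros(space.n)).success)


def feasible_point(space: WeightSpace) -> np.ndarray:
    """Any feasible weight vector (original criterion order).

    Raises :class:`InfeasibleWeightSpaceError` if the space is empty.
    """
    res = _solve(space, np.zeros(space.n))
    if not res.success:
        raise InfeasibleWeightSpaceError(
            "weight space is empty; retract the latest constraint"
        )
    return np.asarray(res.x)


def enumerate_vertices(space: WeightSpace) -> list[np.ndarray]:
    """Extreme points of an ordering-only space with epsilon treated as 0.

    The ordered simplex ``k[r1] >= k[r2] >= ... >= 0, sum k = 1`` has exactly
    ``n`` vertices: for each ``m = 1..n`` the vector putting ``1/m`` on the
    ``m`` top-ranked criteria.  Only valid without tradeoff constraints — the
    oracle exists to cross-check the LP path on spaces where the geometry is
    known exactly.
    """
    if space.constraints:
        raise ValueError(
            "vertex enumeration is only valid for ordering-only spaces"
        )
    n = space.n
    if n > 10:
        raise ValueError("vertex oracle limited to n <= 10")
    out = []
    for m in range(1, n + 1):
        v = np.zeros(n)
        v[list(space.ranking[:m])] = 1.0 / m
        out.append(v)
    return out


def weight_ranges(space: WeightSpace) -> np.ndarray:
    """Per-criterion attainable weight interval, shape (n, 2), original order.

    Solves 2n auxiliary LPs (min and max of each ``k_i`` over the space); the
    published decision system displays the same intervals as a bar chart at
    the end of elicitation.
    """
    n = space.n
    out = np.zeros((n, 2))
    for i in range(n):
        c = np.zeros(n)
        c[i] = 1.0
        lo = _solve(space, c)
        hi = _solve(space, -c)
        if not (lo.success and hi.success):
            raise InfeasibleWeightSpaceError(
                "weight space is empty; retract the latest constraint"
            )
        out[i] = (lo.fun, -hi.fun)
    return out
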