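"""Flexible tradeoff elicitation: questions, answers, and the sorting loop.

Each elicitation cycle shows the decision maker two hypothetical outcomes that
differ on exactly two criteria: option A has criterion *i* (the higher-ranked
of the pair) at a partial performance whose marginal value is ``lambda`` and
every other criterion at its worst level; option B has criterion *j* at its
best level and everything else at worst.  Under the additive model option A is
worth ``lambda * k_i`` and option B ``k_j``, so the answer is a pure probe of
the weight ratio ``k_j / k_i``:

* prefer A  ->  ``k_j / k_i <= lambda``  (constraint ``lambda k_i >= k_j + eps``)
* prefer B  ->  ``k_j / k_i >= lambda``
* indifferent -> the ratio is pinned to ``lambda``
* skip      ->  no information

The default question strategy is deterministic bisection with round-robin over
ranked pairs (adjacent pairs first, then increasing rank distance): for each
pair the open interval of ``lambda`` where the ratio is still undetermined
starts at (0, 1) and halves with every strict answer.  The published decision
system uses an unpublished selection heuristic; bisection is chosen here for
reproducibility, so per-cycle classified counts are not expected to match any
particular interactive session, only to be monotone and to converge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .problem_model import ClassProfile, ConsequenceMatrix, compute_value_matrix
from .sorting_engine import Classification, classify_all
from .weight_space import (
    TradeoffConstraint,
    WeightSpace,
    initial_weight_space,
    is_feasible,
)

__all__ = [
    "Answer",
    "ElicitationQuestion",
    "QuestionGenerator",
    "constraint_from_answer",
    "TraceRow",
    "ElicitationTrace",
    "ElicitationOutcome",
    "run_elicitation",
    "recorded_answer_source",
    "simulated_answer_source",
    "describe_question",
]


class Answer(enum.Enum):
    """A decision maker's reply to one paired comparison."""

    PREFER_A = "a"
    PREFER_B = "b"
    INDIFFERENT = "i"
    SKIP = "s"
    QUIT = "q"

    @classmethod
    def parse(cls, token: str) -> "Answer":
        token = token.strip().lower()
        aliases = {
            "a": cls.PREFER_A, "prefer_a": cls.PREFER_A,
            "b": cls.PREFER_B, "prefer_b": cls.PREFER_B,
            "i": cls.INDIFFERENT, "indifferent": cls.INDIFFERENT,
            "s": cls.SKIP, "skip": cls.SKIP,
            "q": cls.QUIT, "quit": cls.QUIT,
        }
        if token not in aliases:
            raise ValueError(f"unrecognized answer {token!r}")
        return aliases[token]


@dataclass(frozen=True)
class ElicitationQuestion:
    """A paired comparison probing the ratio of two criterion weights.

    ``upper``/``lower`` are ranking positions (0-based, upper ranked higher);
    ``level`` is the marginal value of option A's outcome on the upper
    criterion.  Option A is worth ``level * k_upper``, option B ``k_lower``.
    """

    upper: int
    lower: int
    level: float


def constraint_from_answer(
    q: ElicitationQuestion, a: Answer
) -> TradeoffConstraint | None:
    """Translate an answer into a weight-space constraint (None for skip/quit)."""
    relation = {
        Answer.PREFER_A: "prefer_upper",
        Answer.PREFER_B: "prefer_lower",
        Answer.INDIFFERENT: "indifferent",
    }.get(a)
    if relation is None:
        return None
    return TradeoffConstraint(
        upper=q.upper, lower=q.lower, level=q.level, relation=relation
    )


class QuestionGenerator:
    """Deterministic bisection / round-robin question strategy.

    Maintains, for every ranked pair (i, j), the open interval of ``lambda``
    where the weight-ratio ``k_j / k_i`` is undetermined (initially (0, 1));
    asks the midpoint of the current pair's interval and rotates through the
    pairs ordered adjacent-first.  A pair leaves the rotation when its
    interval is narrower than ``resolution``, when the answer was indifferent
    (ratio pinned), or when the comparison was skipped.
    """

    def __init__(self, n: int, resolution: float = 0.05):
        if n < 2:
            raise ValueError("need at least 2 criteria")
        if not (0.0 < resolution < 1.0):
            raise ValueError("resolution must lie in (0, 1)")
        self.resolution = float(resolution)
        self.pairs: list[tuple[int, int]] = sorted(
            ((i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda p: (p[1] - p[0], p[0]),
        )
        self.intervals: dict[tuple[int, int], tuple[float, float]] = {
            p: (0.0, 1.0) for p in self.pairs
        }
        self.retired: set[tuple[int, int]] = set()
        self._cursor = 0

    def _active(self, pair: tuple[int, int]) -> bool:
        if pair in self.retired:
            return False
        lo, hi = self.intervals[pair]
        return (hi - lo) >= self.resolution

    @property
    def exhausted(self) -> bool:
        return not any(self._active(p) for p in self.pairs)

    def next_question(self) -> ElicitationQuestion | None:
        """The next midpoint question, or None when all pairs are resolved."""
        for _ in range(len(self.pairs)):
            pair = self.pairs[self._cursor % len(self.pairs)]
            self._cursor += 1
            if self._active(pair):
                lo, hi = self.intervals[pair]
                return ElicitationQuestion(
                    upper=pair[0], lower=pair[1], level=0.5 * (lo + hi)
                )
        return None

    def register(self, q: ElicitationQuestion, a: Answer) -> None:
        """Shrink the pair's undetermined interval according to the answer."""
        pair = (q.upper, q.lower)
        lo, hi = self.intervals[pair]
        if a is Answer.PREFER_A:
            # ratio <= level: everything above level is now determined
            self.intervals[pair] = (lo, min(hi, q.level))
        elif a is Answer.PREFER_B:
            self.intervals[pair] = (max(lo, q.level), hi)
        elif a is Answer.INDIFFERENT:
            self.intervals[pair] = (q.level, q.level)
            self.retired.add(pair)
        elif a is Answer.SKIP:
            self.retired.add(pair)

    def retire(self, q: ElicitationQuestion) -> None:
        """Drop the pair from rotation (used after a rejected answer)."""
        self.retired.add((q.upper, q.lower))


def describe_question(
    q: ElicitationQuestion,
    matrix: ConsequenceMatrix,
    ranking: Sequence[str],
) -> str:
    """Render a question in natural units (inverse of the value function).

    Option A carries the upper criterion at the raw performance whose marginal
    value is ``level`` (all other criteria at worst); option B carries the
    lower criterion at its best observed/declared performance.
    """
    name_i = ranking[q.upper]
    name_j = ranking[q.lower]

    def raw_at(name: str, level: float) -> float:
        crit = matrix.criterion(name)
        col = matrix.performance[name]
        rng = crit.declared_range
        if rng is None:
            lo, hi = float(col.min()), float(col.max())
            rng = (hi, lo) if crit.direction == "minimize" else (lo, hi)
        worst, best = rng
        return worst + level * (best - worst)

    raw_i = raw_at(name_i, q.level)
    raw_j = raw_at(name_j, 1.0)
    return (
        f"Option A: {name_i} at {raw_i:g} ({q.level:.0%} performance), "
        f"all other criteria at worst.\n"
        f"Option B: {name_j} at {raw_j:g} (100% performance), "
        f"all other criteria at worst."
    )


@dataclass(frozen=True)
class TraceRow:
    """One elicitation cycle: the question asked, the answer, and the number
    of singly classified alternatives after re-solving the LPs."""

    cycle: int
    question: ElicitationQuestion | None
    answer: Answer | None
    n_classified: int
    rejected: bool = False


@dataclass
class ElicitationTrace:
    rows: list[TraceRow] = field(default_factory=list)

    def append(self, row: TraceRow) -> None:
        self.rows.append(row)

    def __iter__(self) -> Iterator[TraceRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Summary table: cycle, answer, n_classified (plus question params)."""
        return pd.DataFrame(
            {
                "cycle": [r.cycle for r in self.rows],
                "upper": [r.question.upper if r.question else None for r in self.rows],
                "lower": [r.question.lower if r.question else None for r in self.rows],
                "level": [r.question.level if r.question else None for r in self.rows],
                "answer": [r.answer.name if r.answer else "" for r in self.rows],
                "rejected": [r.rejected for r in self.rows],
                "n_classified": [r.n_classified for r in self.rows],
            }
        ).set_index("cycle")


@dataclass(frozen=True)
class ElicitationOutcome:
    trace: ElicitationTrace
    classification: Classification
    space: WeightSpace
    stopped_by: str  # "all_classified" | "quit" | "exhausted" | "max_cycles"


AnswerSource = Callable[[ElicitationQuestion], Answer]


def recorded_answer_source(answers: Sequence[Answer] | pd.DataFrame) -> AnswerSource:
    """Replay a recorded answer sequence; quits when the record runs out.

    Accepts either a plain sequence of :class:`Answer` or a recorded-answer
    table with an ``answer`` column (tokens ``a``/``b``/``i``/``s``).
    """
    if isinstance(answers, pd.DataFrame):
        seq = [Answer.parse(str(tok)) for tok in answers["answer"]]
    else:
        seq = list(answers)
    it = iter(seq)

    def source(q: ElicitationQuestion) -> Answer:
        try:
            return next(it)
        except StopIteration:
            return Answer.QUIT

    return source


def simulated_answer_source(dm) -> AnswerSource:
    """Adapter for a :class:`~fitsort.synthetic_data.SimulatedDM`."""
    from .synthetic_data import simulate_dm_answer

    return lambda q: simulate_dm_answer(dm, q)


def run_elicitation(
    matrix: ConsequenceMatrix,
    profile: ClassProfile,
    ranking: Sequence[str],
    answer_source: AnswerSource,
    *,
    epsilon: float = 1e-6,
    resolution: float = 0.05,
    max_cycles: int = 200,
) -> ElicitationOutcome:
    """Run the interactive sorting loop to one of its stopping conditions.

    Cycle 0 classifies with ordering-only constraints.  Each later cycle asks
    one question, translates the answer into a constraint, re-solves both LPs
    for every alternative and appends a trace row.  Stops when (a) every
    alternative is singly classified, (b) the answer source quits, (c) the
    question generator is exhausted, or (d) ``max_cycles`` is reached.  An
    answer that would empty the weight space is treated as decision-maker
    inconsistency: it is rejected (space unchanged), flagged in the trace,
    and the pair is retired rather than silently relaxed.

    ``ranking`` lists criterion names, most important first.
    """
    names = [c.name for c in matrix.criteria]
    if sorted(ranking) != sorted(names):
        raise ValueError(
            f"ranking must be a permutation of the criterion names {names}"
        )
    ranking = list(ranking)
    perm = tuple(names.index(nm) for nm in ranking)

    values = compute_value_matrix(matrix)
    space = initial_weight_space(perm, epsilon)
    classification = classify_all(values, space, profile)
    trace = ElicitationTrace()
    trace.append(
        TraceRow(0, None, None, classification.n_singly_classified)
    )

    generator = QuestionGenerator(len(names), resolution=resolution)
    stopped_by = "max_cycles"
    cycle = 0
    if classification.n_singly_classified == len(classification):
        stopped_by = "all_classified"
        max_cycles = 0
    while cycle < max_cycles:
        q = generator.next_question()
        if q is None:
            stopped_by = "exhausted"
            break
        a = answer_source(q)
        if a is Answer.QUIT:
            stopped_by = "quit"
            break
        cycle += 1
        rejected = False
        constraint = constraint_from_answer(q, a)
        if constraint is not None:
            candidate = space.with_constraint(constraint)
            if is_feasible(candidate):
                space = candidate
                generator.register(q, a)
            else:
                rejected = True
                generator.retire(q)
        else:
            generator.register(q, a)  # skip: retire the pair
        classification = classify_all(values, space, profile)
        trace.append(
            TraceRow(cycle, q, a, classification.n_singly_classified, rejected)
        )
        if classification.n_singly_classified == len(classification):
            stopped_by = "all_classified"
            break
    return ElicitationOutcome(
        trace=trace,
        classification=classification,
        space=space,
        stopped_by=stopped_by,
    )
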