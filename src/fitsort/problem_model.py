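"""Domain types for multicriteria inventory sorting.

The sorting model evaluates each stock item (an *alternative*) on a handful of
criteria — unit cost, monthly demand, replenishment lead time, an ordinal
criticality rating, storage volume — and aggregates them with an additive value
function ``v(a) = sum_i k_i * v_i(a)``.  This module holds the raw-data side of
that model:

* :class:`Criterion` — a criterion's semantics (optimization direction,
  natural vs. built scale, optional declared worst/best levels);
* :class:`ConsequenceMatrix` — raw performances ``x_ij`` in natural units;
* :class:`ValueMatrix` — normalized marginal values ``v_i(a_j)`` in [0, 1],
  increasing in preference for every criterion;
* :class:`ClassProfile` — the ordered monitoring classes and the thresholds
  ``b_r`` that partition [0, 1] into class bands;
* loaders for the bundled 48-item university-hospital dataset and for the
  published per-alternative value bounds that accompany it.

Marginal value functions are linear over the declared (or observed) range,
worst level -> 0, best level -> 1.  Built ordinal scales (criticality 1-3) are
normalized linearly over their declared levels, i.e. ``(x - 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Criterion",
    "ConsequenceMatrix",
    "ValueMatrix",
    "ClassProfile",
    "MatrixParseError",
    "DegenerateCriterionError",
    "load_consequence_matrix",
    "compute_value_matrix",
    "huol_criteria",
    "huol_fixture",
    "huol_reference_bounds",
    "HUOLFixture",
]

Direction = Literal["maximize", "minimize"]
ScaleKind = Literal["natural", "built"]

_DIRECTION_ALIASES = {
    "max": "maximize",
    "maximize": "maximize",
    "maximization": "maximize",
    "min": "minimize",
    "minimize": "minimize",
    "minimization": "minimize",
}


class MatrixParseError(ValueError):
    """A consequence-matrix file violates the criteria configuration."""


class DegenerateCriterionError(ValueError):
    """A criterion is constant over the alternatives and has no declared range."""


@dataclass(frozen=True)
class Criterion:
    """Semantics of one evaluation criterion.

    Parameters
    ----------
    name
        Column identifier, e.g. ``"lead_time"``.
    direction
        ``"maximize"`` if larger raw values are preferred (demand,
        criticality), ``"minimize"`` otherwise (cost, lead time, volume).
        The aliases ``"max"``/``"min"`` are accepted.
    scale_kind
        ``"natural"`` for measured quantities, ``"built"`` for constructed
        ordinal scales (whose admissible levels are the integers between
        ``worst_level`` and ``best_level``).
    worst_level, best_level
        Optional declared endpoints in natural units.  When absent, the
        observed column range is used at normalization time.
    """

    name: str
    direction: Direction
    scale_kind: ScaleKind = "natural"
    worst_level: float | None = None
    best_level: float | None = None

    def __post_init__(self) -> None:
        direction = _DIRECTION_ALIASES.get(str(self.direction).lower())
        if direction is None:
            raise ValueError(
                f"criterion {self.name!r}: direction must be 'maximize' or "
                f"'minimize', got {self.direction!r}"
            )
        object.__setattr__(self, "direction", direction)
        if self.scale_kind not in ("natural", "built"):
            raise ValueError(
                f"criterion {self.name!r}: scale_kind must be 'natural' or "
                f"'built', got {self.scale_kind!r}"
            )
        if self.worst_level is not None and self.best_level is not None:
            if self.worst_level == self.best_level:
                raise ValueError(
                    f"criterion {self.name!r}: worst_level and best_level coincide"
                )
            increasing = self.best_level > self.worst_level
            if increasing != (self.direction == "maximize"):
                raise ValueError(
                    f"criterion {self.name!r}: best_level must exceed worst_level "
                    f"iff the criterion is maximized"
                )

    @property
    def declared_range(self) -> tuple[float, float] | None:
        """(worst, best) in natural units, or None if not fully declared."""
        if self.worst_level is None or self.best_level is None:
            return None
        return (float(self.worst_level), float(self.best_level))

    def ordinal_levels(self) -> set[int] | None:
        """Admissible levels of a fully declared built scale, else None."""
        if self.scale_kind != "built" or self.declared_range is None:
            return None
        worst, best = self.declared_range
        lo, hi = sorted((worst, best))
        return set(range(int(lo), int(hi) + 1))


@dataclass(frozen=True)
class ConsequenceMatrix:
    """Raw performances of alternatives on criteria, in natural units.

    ``performance`` is indexed by alternative id with one column per criterion,
    ordered as in ``criteria``.
    """

    criteria: tuple[Criterion, ...]
    performance: pd.DataFrame

    def __post_init__(self) -> None:
        criteria = tuple(self.criteria)
        object.__setattr__(self, "criteria", criteria)
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise ValueError("criterion names must be unique")
        if len(criteria) < 2:
            raise ValueError("at least 2 criteria are required")
        df = self.performance.loc[:, names].astype(float)
        if df.shape[0] < 2:
            raise ValueError("at least 2 alternatives are required")
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise MatrixParseError(f"duplicate alternative id(s): {dupes}")
        if not np.isfinite(df.to_numpy()).all():
            bad = df.index[~np.isfinite(df.to_numpy()).all(axis=1)][0]
            raise MatrixParseError(f"non-finite performance in row {bad!r}")
        for crit in criteria:
            levels = crit.ordinal_levels()
            if levels is None:
                continue
            col = df[crit.name]
            ok = col.isin(sorted(levels)) & (col == col.round())
            if not ok.all():
                row = col.index[~ok][0]
                raise MatrixParseError(
                    f"row {row!r}, criterion {crit.name!r}: value "
                    f"{col.loc[row]} outside built-scale levels {sorted(levels)}"
                )
        object.__setattr__(self, "performance", df)

    @property
    def alternatives(self) -> list[str]:
        return list(self.performance.index)

    @property
    def n_alternatives(self) -> int:
        return self.performance.shape[0]

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_csv(self, path) -> None:
        """Write the matrix in the canonical CSV exchange format."""
        out = self.performance.copy()
        out.index.name = "alternative"
        out.to_csv(path)


@dataclass(frozen=True)
class ValueMatrix:
    """Normalized marginal values ``v_i(a_j)`` in [0, 1], aligned with a
    :class:`ConsequenceMatrix`; higher always means more preferred."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
            raise ValueError("marginal values must lie in [0, 1]")

    @property
    def alternatives(self) -> list[str]:
        return list(self.values.index)

    def row(self, alternative: str) -> np.ndarray:
        """One alternative's marginal-value vector, criterion order."""
        return self.values.loc[alternative].to_numpy(dtype=float)


@dataclass(frozen=True)
class ClassProfile:
    """Ordered monitoring classes and the thresholds separating them.

    ``labels`` runs from least to most preferred (most critical last); the
    default (M, B, W) reads: monthly, biweekly, weekly monitoring.  Bands are
    lower-open/upper-closed: the lowest class is ``[0, b_1]``, class *r* is
    ``(b_{r-1}, b_r]`` and the top class is ``(b_{L-1}, 1]``, so a value
    sitting exactly on a threshold belongs to the lower band.
    """

    labels: tuple[str, ...] = ("M", "B", "W")
    thresholds: tuple[float, ...] = (0.4, 0.7)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        thresholds = tuple(float(b) for b in self.thresholds)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "thresholds", thresholds)
        if len(set(labels)) != len(labels) or len(labels) < 2:
            raise ValueError("labels must be >= 2 distinct class names")
        if len(thresholds) != len(labels) - 1:
            raise ValueError("need exactly len(labels) - 1 thresholds")
        if any(not (0.0 < b < 1.0) for b in thresholds):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if any(b2 <= b1 for b1, b2 in zip(thresholds, thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def band_index(self, value: float, tol: float = 1e-9) -> int:
        """Index (0 = least preferred) of the band containing ``value``.

        ``tol`` absorbs solver noise: a value within ``tol`` above a threshold
        is still treated as on the threshold (lower band).
        """
        return int(sum(value > b + tol for b in self.thresholds))

    def band_label(self, value: float, tol: float = 1e-9) -> str:
        return self.labels[self.band_index(value, tol)]

    def preference_rank(self, label: str) -> int:
        """Position of ``label`` in the profile order (higher = preferred)."""
        return self.labels.index(label)


def load_consequence_matrix(path, criteria: Sequence[Criterion]) -> ConsequenceMatrix:
    """Read a consequence matrix CSV and validate it against ``criteria``.

    The file must have a header row whose first column is the alternative id
    and whose remaining columns match the criteria configuration by name (in
    any order; the returned matrix follows the configuration order).
    """
    try:
        df = pd.read_csv(path, dtype={0: str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise MatrixParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected an id column plus criteria columns")
    df = df.set_index(df.columns[0])
    names = [c.name for c in criteria]
    missing = sorted(set(names) - set(df.columns))
    extra = sorted(set(df.columns) - set(names))
    if missing or extra:
        raise MatrixParseError(
            f"{path}: column mismatch (missing {missing or 'none'}, "
            f"unexpected {extra or 'none'})"
        )
    for name in names:
        coerced = pd.to_numeric(df[name], errors="coerce")
        bad = coerced.isna() & df[name].notna()
        if bad.any() or coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise MatrixParseError(
                f"{path}: row {row!r}, column {name!r}: non-numeric value "
                f"{df.loc[row, name]!r}"
            )
        df[name] = coerced
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise MatrixParseError(f"{path}: duplicate alternative id(s): {dupes}")
    return ConsequenceMatrix(criteria=tuple(criteria), performance=df[names])


def _criterion_range(crit: Criterion, column: pd.Series) -> tuple[float, float]:
    """(worst, best) raw levels, declared if available else observed."""
    declared = crit.declared_range
    if declared is not None:
        return declared
    lo, hi = float(column.min()), float(column.max())
    if lo == hi:
        raise DegenerateCriterionError(
            f"criterion {crit.name!r} is constant (= {lo}) and has no declared "
            f"worst/best levels; drop the criterion or declare levels"
        )
    return (hi, lo) if crit.direction == "minimize" else (lo, hi)


def compute_value_matrix(matrix: ConsequenceMatrix) -> ValueMatrix:
    """Linear marginal value functions, worst -> 0, best -> 1, clipped to [0, 1].

    For a maximized criterion ``v = (x - worst) / (best - worst)``; for a
    minimized one the same formula with worst = the largest raw level, so the
    cheapest/fastest/smallest item scores 1.  Values outside a *declared*
    range are clipped rather than extrapolated.
    """
    cols = {}
    for crit in matrix.criteria:
        col = matrix.performance[crit.name]
        worst, best = _criterion_range(crit, col)
        v = (col - worst) / (best - worst)
        cols[crit.name] = v.clip(0.0, 1.0)
    values = pd.DataFrame(cols, index=matrix.performance.index)
    return ValueMatrix(values=values[[c.name for c in matrix.criteria]])


# ---------------------------------------------------------------------------
# Bundled university-hospital (HUOL) dataset
# ---------------------------------------------------------------------------


class HUOLFixture(NamedTuple):
    matrix: ConsequenceMatrix
    profile: ClassProfile
    ranking: tuple[str, ...]


def huol_criteria() -> tuple[Criterion, ...]:
    """The five criteria of the bundled hospital dataset."""
    return (
        Criterion("cost", "minimize"),
        Criterion("demand", "maximize"),
        Criterion("lead_time", "minimize"),
        Criterion("criticality", "maximize", scale_kind="built",
                  worst_level=1, best_level=3),
        Criterion("volume", "minimize"),
    )


def _data_path(name: str):
    return resources.files("fitsort.data").joinpath(name)


def huol_fixture() -> HUOLFixture:
    """The bundled 48-item hospital inventory problem.

    Returns the consequence matrix (48 alternatives x 5 criteria), the class
    profile with labels (M, B, W) and thresholds (0.4, 0.7), and the decision
    maker's criterion ranking, most important first:
    demand > criticality > lead_time > cost > volume.
    """
    with resources.as_file(_data_path("huol_consequences.csv")) as p:
        matrix = load_consequence_matrix(p, huol_criteria())
    profile = ClassProfile(labels=("M", "B", "W"), thresholds=(0.4, 0.7))
    ranking = ("demand", "criticality", "lead_time", "cost", "volume")
    return HUOLFixture(matrix=matrix, profile=profile, ranking=ranking)


def huol_reference_bounds() -> pd.DataFrame:
    """Published per-alternative global-value bounds for the hospital dataset.

    One row per alternative with columns ``s1`` (minimum overall value),
    ``s2`` (maximum overall value) and ``classes`` (the published viable class
    set, most preferred first, joined by ``"|"``).  These bounds are the
    output of the original interactive elicitation session and are shipped as
    *inputs* for the assignment and sensitivity stages; they are not
    recomputable from the consequence matrix alone because they encode the
    decision maker's elicited weight space.
    """
    with resources.as_file(_data_path("huol_reference_bounds.csv")) as p:
        df = pd.read_csv(p, dtype={"alternative": str})
    return df.set_index("alternative")
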