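"""Monte Carlo sensitivity of class assignments to the class thresholds.

The LP bounds ``(s1, s2)`` of an alternative do not depend on where the class
thresholds sit, so threshold robustness can be assessed on fixed bounds: draw
perturbed profiles, reassign viable class sets, and count how often each
alternative keeps its nominal set.  Thresholds are drawn independently and
uniformly from ``[b_r (1 - delta), b_r (1 + delta)]`` — with the default
``delta = 0.10`` and thresholds (0.4, 0.7) that is b1' in [0.36, 0.44] and
b2' in [0.63, 0.77].

Because the draws are uniform and independent, the per-alternative stability
has a closed form (:func:`exact_stability`); the Monte Carlo estimate exists
to mirror the simulation protocol and is cross-checked against the closed
form in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .problem_model import ClassProfile
from .sorting_engine import BAND_TOL, assign_classes, recommend_class

__all__ = [
    "SensitivityReport",
    "perturb_profile",
    "validate_delta",
    "run_sensitivity",
    "exact_stability",
]


def validate_delta(profile: ClassProfile, delta: float) -> None:
    """Reject perturbation widths that could cross thresholds or leave (0, 1).

    Requires ``b_r (1 + delta) < b_{r+1} (1 - delta)`` for consecutive
    thresholds, ``b_1 (1 - delta) > 0`` and ``b_last (1 + delta) < 1``, so
    every drawn profile is a valid profile before any draw is made.
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    b = profile.thresholds
    if b[0] * (1 - delta) <= 0.0 or b[-1] * (1 + delta) >= 1.0:
        raise ValueError(
            f"delta = {delta} pushes a threshold outside (0, 1)"
        )
    for b1, b2 in zip(b, b[1:]):
        if b1 * (1 + delta) >= b2 * (1 - delta):
            raise ValueError(
                f"delta = {delta} lets thresholds {b1} and {b2} cross "
                f"({b1 * (1 + delta):.4g} >= {b2 * (1 - delta):.4g})"
            )


def perturb_profile(
    profile: ClassProfile, delta: float, rng: np.random.Generator
) -> ClassProfile:
    """One random profile with each threshold drawn uniformly in its +-delta band."""
    validate_delta(profile, delta)
    b = np.asarray(profile.thresholds)
    drawn = rng.uniform(b * (1 - delta), b * (1 + delta))
    return ClassProfile(labels=profile.labels, thresholds=tuple(drawn))


@dataclass(frozen=True)
class SensitivityReport:
    """Stability of class assignments under threshold perturbation.

    ``per_alternative`` is indexed by alternative with columns ``nominal``
    (the nominal viable set, "|"-joined), ``group`` (``single``/``multi``)
    and ``stability`` (fraction of draws whose reassigned set equals the
    nominal one).  ``group_stability_single``/``_multi`` are the means over
    the two groups, mirroring a protocol that simulates them separately;
    NaN for an empty group.
    """

    n_draws: int
    delta: float
    seed: int
    metric: str
    per_alternative: pd.DataFrame
    group_stability_single: float
    group_stability_multi: float
    overall_stability: float


def _band_matrix(
    s: np.ndarray, draws: np.ndarray, tol: float = BAND_TOL
) -> np.ndarray:
    """Band index of each value of ``s`` under each drawn threshold vector.

    ``s``: shape (m,); ``draws``: shape (d, L-1).  Returns (d, m) ints.
    """
    # s > b + tol, summed over thresholds
    return (s[None, None, :] > draws[:, :, None] + tol).sum(axis=1)


def run_sensitivity(
    bounds: pd.DataFrame,
    profile: ClassProfile,
    delta: float = 0.10,
    n_draws: int = 10_000,
    seed: int = 0,
    metric: str = "viable_set",
) -> SensitivityReport:
    """Monte Carlo stability of assignments from fixed (s1, s2) bounds.

    Parameters
    ----------
    bounds
        Indexed by alternative, columns ``s1`` and ``s2`` (the LP bounds;
        these do not change when thresholds move).
    delta
        Relative half-width of the uniform perturbation of each threshold.
    metric
        ``"viable_set"`` (default): an alternative is stable in a draw iff
        its perturbed viable class set equals the nominal one.
        ``"recommended"``: stability of the recommended class only.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if metric not in ("viable_set", "recommended"):
        raise ValueError(f"unknown metric {metric!r}")
    validate_delta(profile, delta)

    s1 = bounds["s1"].to_numpy(dtype=float)
    s2 = bounds["s2"].to_numpy(dtype=float)
    nominal = [assign_classes(a, b, profile) for a, b in zip(s1, s2)]
    nominal_lo = np.array([profile.band_index(v) for v in s1])
    nominal_hi = np.array([profile.band_index(v) for v in s2])

    rng = np.random.default_rng(seed)
    b = np.asarray(profile.thresholds)
    draws = rng.uniform(
        b * (1 - delta), b * (1 + delta), size=(n_draws, len(b))
    )
    lo_bands = _band_matrix(s1, draws)
    hi_bands = _band_matrix(s2, draws)
    if metric == "viable_set":
        stable = (lo_bands == nominal_lo[None, :]) & (
            hi_bands == nominal_hi[None, :]
        )
    else:
        # recommended class = most preferred viable = band of s2
        stable = hi_bands == nominal_hi[None, :]
    stability = stable.mean(axis=0)

    group = np.where(nominal_lo == nominal_hi, "single", "multi")
    per_alt = pd.DataFrame(
        {
            "nominal": ["|".join(v) for v in nominal],
            "group": group,
            "stability": stability,
        },
        index=bounds.index,
    )
    single = stability[group == "single"]
    multi = stability[group == "multi"]
    return SensitivityReport(
        n_draws=n_draws,
        delta=delta,
        seed=seed,
        metric=metric,
        per_alternative=per_alt,
        group_stability_single=float(single.mean()) if single.size else float("nan"),
        group_stability_multi=float(multi.mean()) if multi.size else float("nan"),
        overall_stability=float(stability.mean()),
    )


def exact_stability(
    s1: float, s2: float, profile: ClassProfile, delta: float
) -> float:
    """Closed-form probability that a fixed interval keeps its viable set.

    With independent uniform draws and non-crossing perturbation ranges, the
    band of a fixed value depends on each threshold separately, so the
    stability factorizes over thresholds: for each threshold the drawn value
    must stay on the same side of both ``s1`` and ``s2`` as the nominal
    threshold.  Ties (a bound exactly on a drawn threshold) have probability
    zero and are ignored.
    """
    validate_delta(profile, delta)
    prob = 1.0
    for b in profile.thresholds:
        lo, hi = b * (1 - delta), b * (1 + delta)
        width = hi - lo

        def cdf(x: float) -> float:
            if width == 0.0:
                return 1.0 if b < x else 0.0
            return float(np.clip((x - lo) / width, 0.0, 1.0))

        if s1 > b and s2 > b:
            prob *= cdf(s1)  # drawn threshold must stay below both bounds
        elif s1 <= b and s2 <= b:
            prob *= 1.0 - cdf(s2)  # must stay at/above both bounds
        else:
            prob *= cdf(s2) - cdf(s1)  # must stay strictly between them
    return prob
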