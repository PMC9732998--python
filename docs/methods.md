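# Methods

## Model and assumptions

`fitsort` sorts alternatives into ordered classes with an additive
multi-attribute value model under partial information about the scaling
constants. The assumptions baked in:

* **Additivity / compensatory preferences.** A disadvantage on one criterion
  can be offset by an advantage on another; the global value is
  `v(a) = Σ k_i v_i(a)` with `Σ k_i = 1`, `k_i ≥ 0`.
* **Linear marginal value functions.** `v_i` is linear over the declared (or,
  when no levels are declared, the observed) range of criterion *i*, worst
  level → 0, best level → 1; minimized criteria are inverted. Linearity is
  the conventional default for this family of methods; nonlinear or
  piecewise-assessed `v_i` are out of scope. Values beyond a *declared* range
  are clipped, not extrapolated. Built ordinal scales (criticality 1–3) are
  treated numerically and normalized linearly (`(x − 1)/2`): the scale
  definition fixes the level semantics, not their spacing, and equal spacing
  is the minimal assumption.
* **Constant criteria are rejected.** A criterion that is constant over the
  alternatives and has no declared levels cannot be normalized; silently
  assigning it `v ≡ 0` would let it consume weight without influencing the
  sort, so normalization raises instead.
* **Strict importance ranking.** The decision maker ranks the criteria
  strictly; consecutive ranks are separated by a strictness constant
  `ε` (default 1e-6, configurable, validated against `ε < 1/(2n²)` so the
  base system is always feasible). `ε = 0` is accepted too and yields the
  weak-order (ordered-simplex) geometry, which is also what the exact vertex
  oracle assumes.

## Weight space and LPs

Every tradeoff answer about "criterion *i* at marginal value λ vs. criterion
*j* at best" adds one constraint: `λ k_i ≥ k_j + ε` (prefer the first),
`λ k_i + ε ≤ k_j` (prefer the second) or `λ k_i = k_j` (indifference, encoded
without ε since indifference is an equivalence, not a strict relation).
Constraints are allowed between arbitrary ranked pairs, not just adjacent
ones. Updates are non-destructive: refining returns a new space, so an
answer that empties the polytope can be rejected and the previous state kept.

Per alternative, the minimum and maximum global values are obtained by two
LPs over the polytope (HiGHS, via `scipy.optimize.linprog`), solved
explicitly rather than via a dual trick — clarity over micro-optimization;
each LP has n ≤ ~10 variables and is sub-millisecond. Bounds are clipped to
[0, 1]. For ordering-only spaces with ε = 0 the polytope is the ordered
simplex whose n vertices put weight 1/m on the m top-ranked criteria; the
test suite checks LP bounds against these prefix-average extremes to 1e-9
for n ≤ 8.

## Assignment rule

Class bands are lower-open/upper-closed: lowest class `[0, b1]`, middle
`(b1, b2]`, top `(b2, 1]` — a value exactly on a threshold belongs to the
lower band. The viable set of an alternative is every band intersected by
the closed interval `[s1, s2]` (three-class spans are possible in principle);
the recommended class is the most preferred viable one. A tolerance of 1e-9
is applied before band comparisons so LP round-off cannot push a bound across
a threshold.

## Elicitation strategy

The original decision-support system's question-selection heuristic is
unpublished, so `fitsort` uses a deterministic, reproducible default:
bisection with round-robin. For each ranked pair (i, j) the open interval of
λ where the ratio `k_j/k_i` is undetermined starts at (0, 1); the generator
cycles over pairs (adjacent first, then increasing rank distance) asking the
interval midpoint, halving the interval on each strict answer, and retiring a
pair on indifference (ratio pinned), on skip, or when the interval drops
below the resolution parameter (default 0.05). One question per cycle; after
each cycle all LPs are re-solved. The loop stops when every alternative is
singly classified, the answer source quits, the generator is exhausted, or a
cycle cap is hit. An answer that would make the space infeasible is treated
as decision-maker inconsistency: rejected, flagged in the trace, the pair
retired — never silently relaxed. A consequence of the pluggable strategy:
per-cycle classified counts from any particular interactive session are not
reproduction targets, only the monotonicity of the count and the containment
of the truth are.

Interactive mode renders questions in natural units by inverting the value
function (e.g. "demand at 21,697 units (50% performance)"), mirroring how
such questions are posed to a real decision maker.

## Threshold sensitivity

The LP bounds do not depend on the thresholds, so robustness to the class
limits is assessed on fixed bounds: each threshold is drawn independently and
uniformly from `[b_r(1−δ), b_r(1+δ)]` (default δ = 0.10; for (0.4, 0.7) that
is [0.36, 0.44] × [0.63, 0.77]); per draw, viable sets are reassigned and an
alternative counts as stable iff its set equals the nominal one. Uniformity
is the minimal reading of "randomly varied within ±10%". δ values that could
let perturbed thresholds cross or leave (0, 1) are rejected before any draw.
Aggregates are means over (alternative × draw) pairs, reported separately
for the nominally-single and nominally-multi groups; a recommended-class
stability metric is available as an option but is not the default. Because
draws are uniform and independent, the per-alternative stability also has a
closed form (`exact_stability`), which the tests use to validate the Monte
Carlo path (3-standard-error agreement at 10,000 draws); seeded runs are
bit-reproducible.

## Bundled case-study fixtures

The package ships the 48-item hospital consequence matrix (5 criteria:
cost R$, demand units/month, lead time days, criticality 1–3, volume m³),
the (M, B, W)/(0.4, 0.7) profile, the published criterion ranking
demand > criticality > lead time > cost > volume, and the published
per-item (s1, s2) bounds with their class labels.

Two caveats govern how the fixtures may be used:

* The published bounds are **inputs, not recomputation targets**. They encode
  an interactive session whose question sequence is not available, and the
  printed dataset is internally inconsistent with any additive monotone
  model: the insulin-syringe row dominates the surgical-mask row componentwise
  in the consequence matrix yet carries much lower printed bounds. `fitsort`
  therefore reproduces the assignment counts (34 single, 14 two-class, 4
  items involving W) and every class label *from the printed bounds*, and
  does not attempt to re-derive the bounds from the matrix.
* The reported two-class-group stability (94.19%) is not reproducible from
  the printed bounds under any uniform counting rule tried; the closed form
  gives ≈86–89% (this implementation: ≈86.3%). The single-class-group figure
  (87.73%) is reproduced to within about one percentage point (closed form
  88.3%, Monte Carlo ≈88.2–88.7% across seeds). The discrepancy is
  documented rather than resolved; the package reports what its own
  computation yields.

## Synthetic data and what passing tests show

The generator draws hospital-like columns: log-normal costs (μ=3, σ=1.8 on
the log scale, i.e. cents to thousands), negative-binomial demand
(mean 900, dispersion 0.45 — heavy-tailed counts), uniform integer lead
times 2–60 days, categorical criticality with probabilities (0.2, 0.4, 0.4),
log-uniform volumes over 1e-4–7e-2 m³. Columns are independent; real
inventories correlate criteria (expensive items tend to be low-demand), so
synthetic results say nothing about such structure — the generator exists to
validate the *machinery* end-to-end against a known ground truth, not to
emulate a particular hospital. Constant columns are redrawn up to a cap,
then rejected.

The simulated decision maker holds hidden strictly-decreasing weights and
answers every tradeoff question exactly (optionally with an indifference
tolerance τ; default τ = 0, i.e. perfectly consistent — noisy or
intransitive decision makers are out of scope because the method assumes
consistency). Two recovery properties are enforced over 20 seeds: the true
global value always stays inside `[s1, s2]` and the true class inside every
viable set; and with a fine question resolution, ≥90% of alternatives whose
true value is threshold-clear end singly classified in their true class.

## Problem sizes used in the checks

The automated checks run the full 48-item fixture for assignment and
sensitivity (10,000 draws), and 6–10-alternative synthetic problems for the
elicitation-loop properties — small enough that the whole suite solves a few
thousand tiny LPs in well under a minute, large enough to exercise every
code path including rejection of inconsistent answers.
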