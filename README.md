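# fitsort

Multicriteria sorting of hospital inventory items under partial preference
information.

Hospital stock managers traditionally rank items by a single criterion (ABC by
monetary value, VED by criticality, FSN by turnover). `fitsort` implements a
multicriteria alternative: each item is scored on several criteria at once —
unit cost, monthly demand, replenishment lead time, an ordinal criticality
rating, storage volume — and sorted into ordered monitoring classes
(**W** weekly, **B** biweekly, **M** monthly) with an additive value model
whose weights are never elicited exactly.

## The model

Each item *a<sub>j</sub>* gets a global value

> *v(a<sub>j</sub>) = Σ<sub>i</sub> k<sub>i</sub> v<sub>i</sub>(a<sub>j</sub>)*

where *v<sub>i</sub>* are linear marginal value functions mapping raw
performances onto [0, 1] (minimized criteria inverted so that more preferred
is always higher) and the scaling constants *k<sub>i</sub>* sum to 1.
Instead of fixing the *k<sub>i</sub>*, the decision maker only ranks the
criteria and answers paired tradeoff questions ("criterion *i* at 50%
performance vs. criterion *j* at 100%?"); every answer adds one linear
constraint on the weight polytope **φⁿ**. For each item two linear programs
bracket its global value over the current polytope:

> *s₁ = min<sub>k∈φⁿ</sub> v(a<sub>j</sub>)*,  *s₂ = max<sub>k∈φⁿ</sub> v(a<sub>j</sub>)*

and the interval [*s₁*, *s₂*] is intersected with the class bands
M = [0, *b₁*], B = (*b₁*, *b₂*], W = (*b₂*, 1] (defaults *b₁* = 0.4,
*b₂* = 0.7). An item whose interval fits in one band is classified; one that
straddles a threshold keeps several *viable* classes, and the recommendation
rule places it in the most critical of them. A Monte Carlo module measures
how robust the assignments are to ±δ shifts of the thresholds.

The 48-item consequence matrix of the university-hospital case study that
motivated the model ships as a bundled fixture, together with the published
per-item (*s₁*, *s₂*) bounds from the original elicitation session.

## Worked example

```python
from fitsort import (huol_fixture, huol_reference_bounds, classify_from_bounds,
                     count_summary, run_sensitivity)

fx = huol_fixture()                    # 48 x 5 matrix, (M, B, W) profile
bounds = huol_reference_bounds()       # published (s1, s2) per item

result = classify_from_bounds(bounds, fx.profile)
summary = count_summary(result.results, fx.profile)
print("singly classified:", result.n_singly_classified)
print("two viable classes:", summary.n_multi)
print("class involvement:", summary.involvement)

single = bounds.loc[[r.alternative for r in result.results if r.is_single]]
report = run_sensitivity(single, fx.profile, delta=0.10, n_draws=10_000, seed=1)
print(f"single-class stability: {100 * report.group_stability_single:.2f}%")
```

prints

```
singly classified: 34
two viable classes: 14
class involvement: {'M': 18, 'B': 40, 'W': 4}
single-class stability: 88.46%
```

Reading: of the 48 items, 34 are fully resolved and 14 sit between two
viable classes; only 4 items involve the weekly-monitoring class W (two
classified W outright, two in {W, B}), so weekly checks are needed for 4/48
items — a reduction of more than 90%. Under ±10% threshold perturbation
(10,000 uniform draws), the singly-classified group keeps its exact class in
≈88% of draws.

There is also a CLI:

```sh
fitsort classify  --out out/            # bundled dataset, ordering-only info
fitsort elicit    --simulated-weights w.csv --out out/
fitsort sensitivity --delta 0.10 --draws 10000 --seed 1 --out out/
fitsort simulate  --n 48 --seed 7 --out out/   # synthetic problem + ground truth
```

`elicit` with no options runs an interactive session: it renders each
tradeoff question in natural units, accepts `a`/`b`/`i`(ndifferent)/
`s`(kip)/`q`(uit), and writes the trace, the classification report and the
final per-criterion weight ranges.

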