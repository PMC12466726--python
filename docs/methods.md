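# Methods

This note documents the model implemented by `wqbench`, the parameters that
matter, the numerical choices made where the design was open, and what the
synthetic generators do and do not emulate.

## Scope and inputs

The package starts at Welfare Quality (WQ) *principle* scores (GF, GHo, GHe,
AB, each 0–100) or, optionally, criterion-level scores collapsed to
principles by arithmetic mean. Computing criterion scores from animal-based
measures (the official WQ protocol's I-spline/decision-tree machinery) is
out of scope. A trivial mean/frequency aggregation is all that is offered
below the criterion level (`aggregate_criteria`).

`aggregate_criteria` defaults to the mean rather than the sum: principle
scores must stay on the 0–100 scale for the rule classifier and the
profile normalisation to make sense. Sum mode exists behind a flag and
fails loudly if it leaves the scale.

## The WQ rule classifier

Rules are evaluated top-down with strict `>` comparisons and "two/three
principles above" read as *at least* two/three. Both readings were fixed by
requiring that the classifier reproduce the six demonstration farm-period
categories (e.g. a GHe of 20.30 must pass the "above 20" floor, so the
boundary is strict). The classifier is monotone: raising any principle
score never lowers the category (property-tested).

## Benchmark statistics

All three benchmarks are built on the normalised profile
ω = Σ principle/maxprinciple ∈ [0, 4].

- **Past ratio** ω_t/ω_{t−1}: maxima are computed *per period* over that
  period's pool — the statistic compares positions relative to the norm
  group, not absolute scores. It is scale-invariant within a period
  (property-tested).
- **Best percent** ω/4 × 100: always computed from the unrounded profile.
  With the demonstration inputs the profile is 3.285083… → 82.13%, whereas
  the display-rounded 3.29/4 would give 82.25 — a reminder that rounding is
  a display concern only. Full precision is carried everywhere; defaults for
  display are 2 d.p. for ratios/percents and 5 d.p. for sigma.
- **Competitor sigma** (ω_farm − ω_comp)/(ω_max − ω_min) ∈ [−1, 1] when both
  farms lie in the pool range; negative means worse than the competitor; the
  value is reported verbatim, never clamped. The min/max pool is
  caller-supplied configuration: the range anchors may mix periods or even
  include farms outside the panel, so it cannot be inferred and the
  `run_full_pipeline` default (period-t extremes) is only a sensible
  convention, explicitly overridable.

## Fuzzy category systems

Each benchmark value, converted to percent (ratio × 100, ω/4 × 100,
σ × 100), is evaluated against five ordered categories: interior categories
are triangles `(a, b, c)`; the extreme categories (critical, excellent) are
shoulders — clamped ramps saturating at 1 — so that every real value is
covered. Degenerate triangle legs (a = b or b = c) evaluate as vertical
edges. The three shipped systems carry the panel-elicited thresholds:

| system | critical | not acceptable | acceptable | good | excellent |
|---|---|---|---|---|---|
| past | ≤85 … 95 | (85, 95, 102.5) | (95, 102.5, 110) | (102.5, 110, 115) | 110 … ≥115 |
| best | ≤20 … 40 | (20, 40, 50) | (40, 50, 70) | (50, 70, 90) | 70 … ≥80 |
| competitor | ≤−50 … −30 | (−50, −30, −10) | (−30, −10, 10) | (−10, 10, 30) | 10 … ≥30 |

The past and competitor systems are Ruspini partitions (memberships sum to
1 everywhere); the best system over-covers on (70, 90), where the good
triangle's right leg overlaps the excellent plateau — the asymmetry is in
the elicited thresholds and is preserved as stated. Custom systems load
from JSON with the same validation (label order, full domain coverage) and
round-trip thresholds bit-exactly.

**Category assignment** takes the maximum-membership label with ties broken
toward the worse label. The elicitation protocol never states a selection
rule; arg-max is consistent with every worked assignment, and the downward
tie-break is this package's choice — conservatism suits certification use.
Assignment over each preset is a monotone step function of the input
(verified against a dense-grid scan; the best system's good→excellent
crossover sits at 230/3 ≈ 76.67).

The five-level label is collapsed to the four-level WQ scale (the two worst
labels merge into "Not classified") and mapped to a fixed constant: 0.25,
0.50, 0.75, 1.00. Note this matching defuzzification is deliberate — not a
centre-of-gravity computation, which is used only in elicitation.

## Choquet aggregation

The four defuzzified values are aggregated with the discrete Choquet
integral under a fuzzy measure on subsets of {WQ, Past, Best, Competitor}.
Implementation: ascending stable sort keyed secondarily by dimension name
(the worked case ties at 0.50, and a deterministic trace is worth having);
ties contribute zero-width increments, so the tie order cannot affect the
value (the integral equals an independent Möbius-transform expansion on
random measures, property-tested up to n = 5).

The shipped default measure is the expert-elicited capacity. Two decisions
around it:

- μ(full set) was never elicited and **defaults to 1.0** — the standard
  normalisation, and the unique value under which the worked aggregate is
  exactly 0.50·1 + 0.25·0.25 + 0.25·0.25 = 0.625. It is overridable.
- The elicited table is **non-monotone** in places (e.g. μ{Past,WQ} = 0.25 <
  μ{WQ} = 0.35). Validation reports such pairs as warnings rather than
  rejecting the measure: the elicited capacity must still run. Boundary
  violations (μ(∅) ≠ 0, values outside [0, 1]) are hard errors.

The scaled score (×100) is classified into four equal bands, half-open at
the lower edge: [0, 25] Not classified, (25, 50] Acceptable, (50, 75]
Enhanced, (75, 100] Excellent. The printed band edges ("25.01–50.00") are a
2-d.p. rendering; continuous inputs need a total rule, and the half-open
reading supplies it.

## Elicitation

The importance scale maps five linguistic labels to triangles on [0, 0.5].
Only the lower three were stated by the protocol; "important" (0.30, 0.35,
0.40) and "extremely important" (0.40, 0.45, 0.50) continue the evident
arithmetic progression and are configurable. Panel consensus is
parameter-wise triangle averaging followed by the centroid
(a + b + c)/3 — the two maps are affine, so their order is immaterial
(property-tested). Threshold categories are built as mean(a), mean(c) with
peak at the midpoint; a zero-width consensus yields a degenerate spike with
a warning. The midpoint rule applies to *new* elicitations only: the
shipped preset systems are hard-coded from their stated formulas, one of
which (past "not acceptable" (85, 95, 102.5)) has a peak off the midpoint.

## Reliability

Cronbach's α uses sample variances (ddof = 1) with raters as observations
and items as columns; it errors on zero total variance, where the statistic
is undefined. Kendall's W uses mid-ranks with the tie correction
T = Σ(t³ − t) on by default (Likert codes guarantee ties; the convention is
not dictated by the protocol), and the large-sample test χ² = k(n − 1)W on
n − 1 degrees of freedom. Both match independent implementations
(a step-by-step spreadsheet-style oracle and `pingouin`; the mean-Spearman
identity for W) on random matrices. The original panel's raw response
matrices are not published, so the package reproduces the *closed-form
consistency* of the reported statistics (e.g. k(n−1)W ≈ 72.7 for W = 0.699,
k = 8, n = 14) rather than their values.

## Synthetic data

`generate_panel` emulates the stated demonstration world: three commercial
dairy herds over two periods, per-principle means (52.0, 51.5, 37.5, 38.0)
and spreads (3.5, 1.0, 12.0, 3.5) matching that sample's structure (Good
Housing nearly flat across herds, Good Health the most variable principle);
scores are normal draws truncated to [0, 100]. `generate_importance_panel`
emulates an eight-expert panel with tunable consensus (probability of
answering the subset's consensus label vs drifting to an adjacent one);
`generate_rating_matrix` produces 8×14 Likert matrices with a shared latent
item order. Not emulated: correlation between principles within a farm,
period-over-period autocorrelation, systematic expert bias, or missing
data. A green test on synthetic data therefore establishes computational
correctness and calibration of the pipeline, not field validity of the
thresholds.

## Known limitations

- The published demonstration inputs are internally inconsistent in two
  cells (the period-t GHo/AB maxima and the competitor's scores differ
  between the score table and the worked equations). The package takes
  inputs as given and does not arbitrate; the worked-equation inputs are
  treated as configuration when reproducing that case.
- Single pairwise competitor comparison only; no league tables.
- No Mamdani/Sugeno rule-base inference: each benchmark is a scalar
  evaluated against one category system.
- No measure learning (Möbius/k-additive fitting); measures come from
  elicitation or files.
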