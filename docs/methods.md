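# Methods

## Model overview

`servgap` treats a service-quality study as three chained operations on
trapezoidal fuzzy numbers.

**Encoding.** A linguistic answer [S_m, S_n] on a scale with maximum base
index T maps to

    A = ( max{(2m−1)/(2T+1), 0},  2m/(2T+1),  (2n+1)/(2T+1),  min{(2n+2)/(2T+1), 1} ),

a trapezoid on [0, 1] whose plateau covers the chosen terms and whose
support overlaps the neighbouring ones. The denominator 2T+1 is taken as
given by the source method; it is mildly asymmetric (the encoding of S_0
is narrower on the left than S_T is on the right), yet the defuzzified
values of mirror terms S_t and S_{T−t} still sum to exactly 1 — the test
suite asserts this identity rather than the weaker "approximate symmetry"
one might expect. Multi-granularity unification is implicit: each value
is encoded with its *own* scale's T, after which trapezoids from
different scales are directly commensurable; no separate
granularity-transformation function exists.

Scales may declare an extended maximum index T′ > T for out-of-scale
judgements. The printed encoding clamps only the first component at 0
and the last at 1; for indices above T the inner components would
overtake the clamped outer ones, so this implementation clamps all four
components to [0, 1] (the encoding then saturates at the top of the
scale). An optional `clamp` mode at value construction snaps wild
indices into range instead of raising.

**Componentwise algebra.** Sums, products, scalar multiples and means act
coordinate by coordinate. Subtraction and division are also
componentwise — as the source algebra prints them — which can break the
a ≤ b ≤ c ≤ d ordering; those two operations therefore return a
`SignedTuple` carrying an `ordered` flag, and nothing ever silently
re-sorts components. This matters in exactly two places:

* *Fuzzy expert weights.* The literal weighted-average formula multiplies
  ratings by linguistic weights and divides by their fuzzy total. The
  componentwise quotient is non-standard and may be unordered, so this
  path sits behind `allow_fuzzy_weights=True` and warns. The validated
  configuration — and the only one exercised by the case study — is equal
  crisp weights, under which the formula reduces exactly to the plain
  componentwise mean (property-tested).
* *Gaps.* The perception–expectation difference is taken after
  defuzzification. Since the defuzzifier is linear, the crisp difference
  equals the defuzzified fuzzy difference exactly (asserted at 1e−12), so
  the reporting path loses nothing.

**Defuzzification.** The segmentation-integral value
P(A) = (a + 2b + 2c + d)/6. It is linear, lies inside the support for
ordered tuples, and does not require ordering.

**Membership.** Piecewise linear with plateau [b, c]. When a ramp is
degenerate (a = b or c = d) the printed formula divides by zero; the
implementation treats the ramp as a step, i.e. membership 1 at the
plateau edge — the right/left limit convention.

## Screening

For indicator i with panel-mean trapezoid f\*, the similarity to each
reference-term encoding M_θ (θ = 0..T of the reference scale) is the
scaled L1 measure Y = 1 − ¼ Σ_h |f\*_h − M_θ^h|, computed componentwise on
the 4-tuples. (Read as a scalar the formula cannot reproduce the
published similarity table — defuzzified inputs give 0.9231 for the first
cell against 0.9641 printed — while the componentwise reading reproduces
every cell to printed-input precision, so componentwise it is.)
1 − Y is a metric on 4-tuples; similarity is symmetric and equals 1 iff
the tuples coincide (property-tested).

The argmax reference term classifies the indicator through a configured
zone partition of term indices. Default for the 7-term scale: remove
{0, 1, 2}, review {3}, keep {4, 5, 6}; for other granularities the lower
half removes, the upper half keeps, and the exact middle index (present
when T is even) reviews. Ties at the argmax — two similarities within
1e−9 — always force "review": borderline calls belong to humans.
"Review" indicators are resolved by a declarative `MergePlan` (explicit
source → target rules for indicators and dimensions); merges encode
expert judgement and are deliberately never inferred from the data.
Merge targets take the position of their first source, which keeps
hierarchy ordering deterministic.

## Gap analysis

Per indicator: AP and AE are the componentwise means of the encoded
perception and expectation answers over all respondents; P and E their
defuzzified values; GAP = P − E on the unrounded values. Dimension rows
are unweighted componentwise means of their sub-indicators' AP/AE
trapezoids — the roll-up rule is not stated in the source text but is the
unique simple rule that reproduces the two dimension rows that *are*
derivable from the printed sub-indicator tables (see "Reproduction
quality" below).

**Key-factor ranking** sorts by ascending *signed* gap — a strongly
positive gap is a strength, so magnitude ranking would misread it — at
reporting precision (3 decimals, half-up) with the indicator id as
tie-break. Ranking at report precision is a deliberate choice: the two
worst published gaps (−0.0305 and −0.0310 unrounded) are
indistinguishable at the precision the study reports, and treating them
as a tie with a deterministic id order is more honest than an ordering
that hinges on the fourth decimal of rounded inputs.

**Rounding convention.** All computation is full precision; reports round
half-away-from-zero, 3 decimals for P/E/gap and 4 for similarities
(the published tables round 0.7225 → 0.723, which fixes the half-up
convention). The helper guards at 12 decimals first so binary float
noise an ulp below a tie still rounds up.

## Synthetic data generator

The generator emulates the case-study shape: 15 equally weighted experts
rating 24 indicators, and 434 respondents (of 691 collected, a 62.8%
valid rate — validity screening itself is upstream and enters only as
this count) giving paired perception/expectation answers on the 7-term
scale over the optimized 19 indicators.

* **Planted truth.** Importance terms default to each indicator's
  published similarity argmax; survey levels default to perception one
  term below expectation (S_4 vs S_5) where the published gap is
  negative and the reverse where positive. Both are maps the caller can
  replace.
* **Mixed granularity.** Experts alternate between the 7-term and 5-term
  scales (8 vs 7 of 15). A planted canonical term t maps to a coarser
  scale by proportional index scaling round_half_up(t · T_expert / T_canon).
* **Noise.** With probability `noise_prob` (default 0.1) an answer moves
  one term up or down (equal probability, clipped to the scale); with
  probability `interval_prob` (default 0.05, a modest hesitation rate)
  the answer widens to a two-term interval. This is the minimal
  structure-preserving ordinal noise model; the source gives none.
* **Determinism.** All draws come from a seeded generator; identical spec
  + seed reproduce outputs byte-for-byte through the CSV writers.

What passing the recovery tests shows: with this noise level and these
sample sizes the pipeline recovers planted screening zones (≥95% over
200 seeds) and gap signs (≥99% over 50 seeds). What it does not show:
robustness to respondent covariates, non-response, acquiescence or
scale-use heterogeneity — none of which are modelled.

## Reproduction quality and known source inconsistencies

The packaged fixtures transcribe the published tables as printed, with
two obvious typographic corrections in the panel-mean table ("0301" →
0.301; "0.864.0.932" → 0.864, 0.932), flagged in
`fixtures.TYPO_CORRECTIONS`. Recomputing the downstream tables from
those printed inputs reproduces:

* all 24 similarity-argmax columns, and 162 of the 168 similarity cells
  within ±0.0005; six cells deviate by 0.00055–0.0007, the precision
  loss expected when the published table was computed from unrounded
  panel means of which only 3 decimals are printed;
* the crisp P/E/gap columns of 18 of the 19 sub-indicator rows within
  ±0.001 — the remaining row (C_14) prints P = 0.715 and gap = −0.005
  that are inconsistent with its *own* printed AP tuple (which
  defuzzifies to 0.7025); the tuple, not the crisp cells, is consistent
  with the dimension roll-up, so the fixture keeps the table as printed
  and the discrepancy is surfaced by the tests rather than patched;
* dimension rows C_1 and C_2 exactly (within ±0.001) as unweighted
  means of their sub-indicators; rows C_3 and C_4 are *not* derivable
  from the printed sub-indicator table (C_3 off by ~0.002, C_4's AP by
  ~0.037 with a gap sign flip), an internal inconsistency of the source
  tables that no roll-up rule can reconcile.

## Numerical choices and degenerate inputs

* Trapezoid construction validates ordering and finiteness; unordered
  results of subtraction/division are representable only as
  `SignedTuple`.
* Similarity warns (does not raise) on non-normalised inputs, since the
  value may then leave [0, 1].
* Aggregation is strict about missing cells by default; the optional
  `missing="drop"` policy drops a respondent for that indicator only,
  independently per grid, and errors if nothing remains.
* Empty collections, zero total weight, mixed crisp/fuzzy weight
  vectors, empty dimensions, malformed zone partitions and merge plans
  touching removed or unknown indicators all raise with specific
  messages.
* Means of n identical tuples are exact only to float round-off; tests
  assert 1e−12, not bit equality.

## Limitations

The method itself performs no statistical inference — gaps carry no
confidence intervals and no significance tests, and none are added here.
The componentwise division is kept for fidelity and is not a valid fuzzy
arithmetic in the extension-principle sense. The generator's noise model
is ordinal and symmetric; real questionnaire noise is richer. Alternative
defuzzifiers (centroid, mean-of-maxima) and α-cut arithmetic are out of
scope.
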