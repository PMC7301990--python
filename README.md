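# servgap

Service-quality evaluation from **multi-granularity linguistic survey
data**: trapezoidal-fuzzy encoding of verbal ratings, similarity-based
indicator screening, and SERVQUAL-style perception–expectation gap
analysis.

## The problem

Quality-of-service studies (the motivating case is teleconsultation — the
referring "regional" doctors who actually use a telemedicine platform)
collect two kinds of judgements:

* **expert importance ratings** used to prune an initial indicator system,
  and
* **respondent surveys** with paired *perception* and *expectation*
  answers per indicator.

Raters rarely give crisp numbers. They answer on ordered verbal scales
S = {S_0, …, S_T} — and different raters prefer different granularities
(a 5-term scale for one expert, a 7-term scale for another), sometimes
hedging with an interval [S_m, S_n] of adjacent terms. `servgap`
implements the full pipeline that makes such data commensurable and turns
it into actionable rankings.

## The method

1. **Encoding.** Every answer [S_m, S_n] on a scale with maximum index T
   becomes a trapezoidal fuzzy number on [0, 1]:

   ```
   A = ( max{(2m−1)/(2T+1), 0},  2m/(2T+1),  (2n+1)/(2T+1),  min{(2n+2)/(2T+1), 1} )
   ```

   Because each value is normalised with its *own* scale's T, mixed
   granularities aggregate directly.

2. **Aggregation.** Panels and surveys are averaged componentwise
   (optionally expert-weighted): AP and AE are the mean perception and
   expectation trapezoids per indicator.

3. **Screening.** Each indicator's panel-mean trapezoid f\* is matched to
   the reference scale encodings M_θ through the scaled-L1 similarity
   `Y(f*, M_θ) = 1 − ¼ Σ_h |f*_h − M_θ^h|`. The argmax term's zone decides:
   unimportant end → remove, middle → review (resolved by an explicit
   expert merge plan), important end → keep.

4. **Gap analysis.** Crisp scores come from the segmentation-integral
   defuzzifier `P(A) = (a + 2b + 2c + d)/6`; the quality gap per indicator
   is `GAP = P − E`, rolled up to dimensions as unweighted means, with key
   factors ranked by most negative gap.

A synthetic-data module generates expert panels and surveys with planted
true levels, ordinal ±1-term noise and occasional interval answers, so the
whole pipeline is testable end to end without the original questionnaires.

## Worked example

The packaged fixtures transcribe the published case-study tables
(24-indicator expert panel, 19-indicator gap report over 434 valid
questionnaires out of 691 collected):

```python
from servgap import fixtures, similarity
from servgap.fuzzy import round_half_up

ref = fixtures.load_fixture("termset_7")          # 7-term reference scale
f1 = fixtures.table3_trapezoids()["network-service-provider"]
round_half_up(similarity(f1, ref.encode(2)), 4)   # -> 0.9642
```

The indicator's panel mean sits closest to S_2 ("slightly poor"
importance), so screening removes it. The gap report rebuilt from the
printed AP/AE trapezoids ranks the key factors:

```python
report = fixtures.gap_results_from_table6()
for iid, gap in report.rank_key_factors(5):
    print(f"{iid:25s} {gap:+.3f}")
```

```
operators-attitude        -0.031
turnover-rates            -0.031
consultation-duration     -0.029
charges                   -0.026
experts-attitude          -0.025
```

These five indicators fall shortest of respondent expectations (the first
two tie at the reported precision); at dimension level the worst gap is
`report.rank_key_factors(1, level="dimension")` →
`[('structure-quality', -0.019)]` — resource allocation is the weakest
dimension.

The same pipeline runs from the shell on synthetic data:

```bash
servgap simulate --seed 11 --out demo
servgap screen --ratings demo/ratings.csv --merge-plan paper --out demo/screen
servgap evaluate --survey demo/survey.csv \
    --hierarchy demo/screen/optimized_hierarchy.json --out demo/eval
```

which prints, for the screening step:

```
experts: f=15; indicators screened: 24
decisions: keep=18 review=4 remove=2
removed: network-service-provider, appointment-channel
optimized hierarchy: 19 indicators in 4 dimensions -> demo/screen
```

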