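# Methods

## Model and assumptions

The package builds composite indices over a panel of `n` indicator
variables observed at `T` consecutive periods. The construction assumes:

* every variable can be harmonised to "higher is better" by one of three
  orientation rules (stimulant pass-through, destimulant `min(x)/x`,
  nominant `x/c` / `c/x`), which requires strictly positive values for
  the two converting rules — a zero or negative destimulant (e.g. a
  budget surplus recorded as a negative deficit) is rejected, not
  clamped, because clamping would silently distort the benchmark vectors;
* the relative importance of the variables is an *expert judgement*, not
  a statistical estimate: it enters through a DEMATEL impact matrix and
  is propagated to weights through deterministic closed forms;
* the composite is a weighted sum of benchmark ratios, so it is invariant
  to rescaling any single raw stimulant (the ratio to its own max/min is
  scale-free) and needs no further normalisation of the inputs.

### DEMATEL

The impact matrix holds integers on a 0–3 scale (0 none, 1 small,
2 large, 3 huge) with a zero diagonal; the scale bound is configurable
and can be disabled. Normalisation divides by
`λ = max(max row sum, max column sum)`. The total-influence matrix is the
closed form `T = B_N (I − B_N)⁻¹`, evaluated by a linear solve of the
transposed system — never an explicit inverse — and guarded by a spectral
radius check: inputs with `ρ(B_N) ≥ 1 − 1e−9` raise a convergence error
naming the offending radius. (With `λ` taken over both row and column
sums this is rare — it needs a matrix whose extreme row and column sums
coincide, e.g. a symmetric 2×2 pattern — but it is possible, so it is
checked.) The closed form and the truncated power series
`Σ_{k=1..200} B_N^k` agree to 1e−9 on random admissible matrices; the
closed form is used throughout.

The relation indicator is `t⁻ = Σⱼ t_ij − Σⱼ t_ji` (row minus column
sum). Its across-variable sum is exactly zero, an identity the tests
enforce at machine precision.

### Ranking and weights

Rank 1 denotes the most significant variable: the surrogate-weight
formulas all give their largest weight to rank 1, which fixes the
direction unambiguously. Ties receive fractional (average) ranks; all
four schemes accept fractional ranks, and the resulting weights are
renormalised to sum exactly 1 (for untied permutations the closed forms
already sum to 1 and the renormalisation is a no-op up to rounding).
Negative K scores — possible when a variable is a strong net receiver
with `t⁻ < −t⁺` — are passed through with a warning rather than clipped,
because any clipping rule would be arbitrary; none of the shipped
matrices produce one. The rank-exponent power is validated as `p > 0`;
the default sweep is `{0.5, 1.5, 2, 2.5, 3, 3.5}` (p = 1 duplicates the
rank-sum scheme and is omitted).

### Index variants

* dynamic: base period = `t − base_offset` (default the previous period);
  undefined for the first `base_offset` periods, so the series starts
  later — no value is imputed;
* optimistic / pessimistic: benchmarks are componentwise maxima / minima
  of the converted panel over the same window as the evaluated series,
  current period included; an expert-supplied benchmark vector may be
  passed instead;
* "no weights" means uniform weights `1/n`, keeping the weight sum at 1
  so a benchmark period scores exactly 100.

### Comparison layer

Series are standardised by their own maximum before distance computation,
which preserves within-series ordering. Pearson significance uses the
t-distributed transform of `r` (scipy's default); Spearman significance
uses the large-sample approximation for `n ≥ 10` and an exact permutation
enumeration below that. Correlations of constant series are reported as
NaN with a warning and masked insignificant, never silently zeroed.
Median-difference tests default to Mood's median test with
Kruskal–Wallis as an option; grouping of a KPI family is exposed by
variant, ranking method and weighting scheme, and all three reports are
produced, since any of them can be the relevant policy contrast.

## Synthetic data

The generator emulates the *statistical envelope* of two decades of
annual national statistics for a converging European economy — location,
spread and hard min/max bounds per series — not any country's actual
trajectory. Defaults (units in parentheses):

| series | model | bounds | centre / spread |
|---|---|---|---|
| gdp (currency, millions) | geometric drift × lognormal noise (log-sd 0.03) | [748,483; 2,287,738] | drift spans the bounds over the window |
| remuneration (index, prev. year = 100) | iid normal | [100.1, 105.9] | mean 103, sd 1.78 |
| inflation (index, prev. year = 100) | AR(1), φ = 0.5, innovation sd 2.5 | [99.1, 110.1] | mean 102.5 (also the nominant target) |
| unemployment (%) | random walk, step sd 1.5 | [5.2, 20.0] | start uniform in the central half |
| budget_deficit (currency, millions) | iid normal | [10,406; 46,160] | mean 29,637, sd 10,895 |

Values leaving the bounds are clipped and the clipping is logged. The
noise scales were chosen once so that (a) 20-period paths look like
plausible annual macro series and (b) the oversampled (2,000-period)
empirical extremes come within 5% of the bounds — a shape check on the
generator itself. The survey-style social panel uses AR(1) scores on a
0–100 scale (innovation sd 15, φ = 0.6, bounds [5, 95]); no real survey
underlies it, so the scale is a configurable placeholder. Sense of
threat is generated as a destimulant — more perceived threat is worse —
and the other four scores as stimulants.

What passing tests on synthetic panels do show: every structural
guarantee of the pipeline (bounds of the optimistic/pessimistic index,
benchmark attainment, determinism under seeding, metric and correlation
structure). What they do not show: agreement with any historical index
values, which depend on the undeposited original series; the published
per-year medians are therefore out of scope and only the expert-matrix
stages are checked against published numbers.

## Numerical choices

* Tolerances: weight sums are asserted to 1e−12; the relation-sum
  identity to 1e−10; series-vs-closed-form agreement to 1e−9; published
  reference values to ±0.001 (their printed precision; two entries
  printed with six digits to ±1e−5).
* Reference weight tables are reproduced from full-precision indicators,
  not their 3-decimal printed roundings; the ±0.001 tolerance absorbs
  the difference.
* Dynamic index at the first period: undefined, dropped (no imputation).
* Degenerate inputs (all-zero impact matrix, zero benchmark component,
  non-positive standardisation input, empty groups in median tests) all
  raise typed errors rather than returning sentinel values.
* CSV writers use a fixed `%.10g` float format so identical runs are
  byte-identical.

## Open design points resolved

* Panels with a single series are accepted (useful for unit composition),
  although a composite over one variable is trivially that variable.
* Only the point-target nominant rule is implemented; an asymmetric
  acceptable band would need a second rule that the construction does
  not define.
* No group aggregation of multiple expert matrices: one consensus matrix
  per family. No AHP/BWM-style elicitation families.
* Plotting is left to the caller; all outputs are tidy CSVs that drop
  directly into pandas/seaborn.

## Known limitations

* The destimulant window minimum makes converted values depend on the
  loaded window: extending the panel can rescale a whole converted
  series. This mirrors the benchmark-relative design but means indices
  from different windows are not directly comparable.
* The synthetic generator matches bounds and rough spread, not
  autocorrelation structure or cross-variable dependence (series are
  generated independently); findings about correlation *between weighting
  choices* transfer, findings about macro co-movement would not.
* Mood's median test with many tied values loses power; for short series
  the Kruskal–Wallis option is often preferable.
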