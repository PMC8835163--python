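# kpibench

Composite key-performance indicators (KPIs) for health-system decision
support. Health-care outcomes depend not only on hospitals but on the
economy and the social climate around them; policy analysts therefore need
a small number of composite indices that condense several macro or survey
indicators into one benchmark-relative number per year. `kpibench`
implements that construction end to end, for analysts and researchers who
want the whole chain — expert judgement, weighting and index computation —
reproducible and testable.

## Method

The pipeline has six stages:

1. **Orientation harmonisation.** Each indicator is a *stimulant* (higher
   is better), *destimulant* (lower is better; converted as
   `x' = min_t(x) / x`) or *nominant* (target `c` is best; converted as
   `x' = x/c` below and `c/x` above the target). Converted series lie in
   `(0, 1]`.
2. **DEMATEL influence analysis.** An expert impact matrix `B` (integer
   judgements 0–3, zero diagonal) is normalised by
   `λ = max(max row sum, max column sum)` and expanded into the
   total-influence matrix `T = B_N (I − B_N)⁻¹`, which accumulates direct
   and all indirect effects. Row/column sums of `T` give each variable's
   *prominence* `t⁺ = R + C` and *relation* `t⁻ = R − C` (net cause vs
   net effect; the relations sum to zero).
3. **Importance scores.** Two condensations of `(t⁺, t⁻)`: the Euclidean
   norm (**BD**) and the half-sum `(t⁺ + t⁻)/2` (**K**), each normalised
   to sum 1. Ranking can also use `t⁺` alone (**T+**).
4. **Surrogate weights.** From a rank vector, closed-form schemes: rank
   sum (RS), rank exponent RE(p), rank reciprocal (RR), rank-order
   centroid (ROC) — or the BD/K scores used directly as weights.
5. **Benchmarks.** Componentwise best (`x_best`) and worst (`x_worst`)
   observed vectors of the converted panel, or the previous period.
6. **Composite index.** `KPI_t = 100 · Σᵢ wᵢ · x'ᵢ,t / benchᵢ` in three
   variants: *dynamic* (previous period; >100 means improvement),
   *optimistic* (vs `x_best`, always ≤ 100) and *pessimistic* (vs
   `x_worst`, always ≥ 100).

A comparison layer standardises the resulting family of series
(`KPI' = KPI / max KPI`), and reports Euclidean distances, Pearson and
Spearman correlation matrices with 0.05-level significance masks,
direction-consistency counts, and nonparametric median-difference tests
(Mood's test by default) between variants, ranking methods or schemes.

Because the original national statistics behind the worked example are
not deposited, the package ships a seeded synthetic generator emulating
their published envelope: a growing GDP series, a real-wage index near
100–106, an inflation index around the 102.5 target, a bounded
unemployment rate, and a positive budget deficit — plus a survey-style
0–100 social panel.

## Worked example

```python
from kpibench import datasets, weighting, convert_panel, kpi_family, generate_economic_panel
from kpibench.dematel import analyse

indicators = analyse(datasets.economic_impact_matrix())
print(indicators.to_frame().round(3))
```

```
                t_plus  t_minus
variable
gdp             19.871   -0.225
remuneration    19.370    0.799
inflation       17.601    0.553
unemployment    20.307    0.212
budget_deficit  11.899   -1.339
```

The labour-market variable (measured as the registered unemployment rate)
has the largest prominence (20.307): it is the most involved in the
dependency structure. The budget deficit has the most negative relation
(−1.339): it is predominantly an effect of the other variables.

```python
weights = weighting.weight_table(indicators)
panel = generate_economic_panel(seed=1)
family = kpi_family(convert_panel(panel), weights[panel.names])
print(family.groupby("variant")["value"].median().round(2))
```

```
variant
dynamic        103.21
optimistic      80.47
pessimistic    140.17
```

On this synthetic panel the median dynamic index is above 100 (year-on-year
improvement on average), the optimistic index sits about 20% below the
best-case benchmark, and the pessimistic index about 40% above the
worst-case one.

The same chain is available from a shell:

```bash
kpibench simulate --seed 1 --out panel.csv --config-out config.yaml
kpibench dematel  --matrix economic --out indicators.csv
kpibench weights  --matrix economic --out weights.csv
kpibench kpi      --panel panel.csv --config config.yaml --matrix economic --out kpi.csv
kpibench compare  --kpi kpi.csv --out-prefix cmp
```

Reruns with the same seed produce byte-identical files.

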