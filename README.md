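# vlwelfare

Monetizing disease burden with the value-of-a-statistical-life-year
(VSLY) framework.

Burden-of-disease studies report health loss in disability-adjusted
life years (DALYs); health economists and policy analysts often need
that loss in money, comparable across countries, to weigh prevention
and treatment investment against other uses of public funds.
`vlwelfare` implements the standard welfare-based chain for doing so at
global scale — e.g. for colorectal cancer across 204 countries and
territories — from raw GBD-style and World-Bank-style tables to
regional league tables:

1. **Benefit transfer** — a benchmark value of a statistical life
   (VSL, default $11.8 million for the United States, 2021) is scaled
   to each country by income:
   `VSL_i = VSL_bench × (GDP_pc,i / GDP_pc,bench)^ε`,
   with income elasticity ε (base 1.0; sensitivity 0.55, 1.5).
2. **Per life year** — `VSLY_i = VSL_i / (LE_i / 2)`, half the national
   life expectancy approximating average remaining life years; a
   discounted variant annuitizes the same span at rate r (default 3%):
   `VSLY_disc = VSL / a(r, LE/2)` with `a(r, n) = (1 − (1+r)^−n)/r`.
3. **Value of lost welfare** — `VLW_i = DALY_i × VSLY_i` and
   `%GDP_i = 100 × VLW_i / GDP_i`, applied to the central estimate and
   both ends of the 95% uncertainty interval.
4. **Aggregation** — sums over the GBD hierarchy (21 regions, 7
   super-regions, 5 SDI quintiles, global) with ratio-of-sums GDP
   shares, plus national median/IQR summaries and sensitivity-grid
   comparisons.

A synthetic-data generator produces inputs in the exact file dialects
the readers consume (with a truth ledger for closure testing), so the
whole pipeline is testable without downloads.

## Worked example

```python
from vlwelfare import ValueOfLostWelfare, make_toy3

model = ValueOfLostWelfare.from_bundle(make_toy3())
res = model.fit(elasticity=1.0, discount_rate=0.03)
print(res.summary())
```

```
Value of Lost Welfare — valuation results
=========================================================
Countries: 3    Year: 2021
Benchmark: Benchia (VSL 11.8M, GDP pc 64,000)
Income elasticity: 1.0    Discount rate: 3.00%
---------------------------------------------------------
Global VLW (millions): 15,958.10 [12,766.48 – 19,149.71]
Global VLW/GDP (%):    0.21 [0.16 – 0.25]
---------------------------------------------------------
National VLW median (millions): 1,123.81 (IQR 604.05 – 7,936.90)
National VLW/GDP median (%):    0.11 (IQR 0.10 – 0.17)
  range 0.09 (Crestia) to 0.23 (Benchia)
Discounted national medians: VLW 1,991.45M, VLW/GDP 0.17%
Discount uplift range (%): 62.89 to 77.21 (Crestia)
```

The fixture has three countries: Alandia earns a quarter of the
benchmark income, so its VSL is 11.8M × ¼ = $2.95M; spread over half
its 70-year life expectancy that is $84,285.71 per life year, and its
1,000 DALYs become a welfare loss of $84.29M — 0.1054% of its $80B
GDP. Benchia *is* the benchmark (VSL $11.8M regardless of ε), and
Crestia, at twice the benchmark income and unit elasticity, gets
$23.6M. Discounting at 3% raises every country's loss — by +62.9% at
LE 70 up to +77.2% at LE 84 — because annuitizing the half-life span
raises the value per life year.

```python
res.country_table()           # Table-1-style country rows (millions)
res.aggregate("super_region") # ratio-of-sums regional roll-up
res.national_summary()        # medians, IQRs, extremes, uplift range
```

Sensitivity grid and synthetic worlds:

```python
from vlwelfare import WorldSpec, generate_world, run_scenarios, default_grid

world = generate_world(WorldSpec(n_countries=204, seed=42))
model = ValueOfLostWelfare.from_bundle(world)
bundle = run_scenarios(model, default_grid())   # ε ∈ {0.55,1,1.5} × discounting
bundle.comparison                               # global VLW / %GDP per scenario
```

## Command line

```sh
vlw synth --seed 42 --countries 204 --out world/
vlw run --daly world/daly.csv --econ world/econ.csv \
        --hierarchy world/hierarchy.csv --out results/
vlw scenarios --daly ... --econ ... --hierarchy ... \
        --grid 0.55,1.0,1.5 --discount on,off --out results/
```

`vlw run`/`vlw scenarios` accept a YAML config (`vsl_benchmark`,
`benchmark_location`, `elasticity_grid`, `discount_rate`, `year`,
`output_precision`, …) and log per-stage record counts to stderr.

Real analyses use a GBD results-tool export (DALYs, Number metric, both
sexes, all ages) and WDI tables of GDP per capita (PPP, constant 2021
Int$), population and life expectancy, plus a location-hierarchy CSV;
name variants between the two sources are resolved by an alias table
and gaps are filled by linear interpolation and regional donor means
(see `docs/methods.md`).

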