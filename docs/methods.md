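# Methods

## The model

`vlwelfare` monetizes a disease's burden — disability-adjusted life
years (DALYs) — into a **value of lost welfare (VLW)**, country by
country, and aggregates it over the GBD location hierarchy. The chain
has four deterministic steps.

**1. Benefit transfer of the VSL.** A benchmark value of a statistical
life, `VSL_bench` (default $11.8 million, the 2021 U.S. Department of
Transportation figure), is transferred to country *i* by income:

    VSL_i = VSL_bench × (gdp_pc_i / gdp_pc_bench)^ε

where `gdp_pc` is GDP per capita (PPP, constant 2021 Int$) and ε is the
income elasticity of willingness to pay for mortality-risk reduction
(base case ε = 1.0; sensitivity grid 0.55 and 1.5). The transfer is
unbounded: economies richer than the benchmark receive a VSL above
`VSL_bench`. The benchmark's per-capita GDP is read from the same
economic table as every other country's, never hard-coded, so the
transfer ratio is consistent with the input vintage. The benchmark VSL
(a USD figure) and PPP international dollars are treated as one
numéraire at the benchmark economy; no currency conversion is applied.

**2. Value of a statistical life year.**

    VSLY_i = VSL_i / (LE_i / 2)

with `LE_i` the national life expectancy at birth. Half the life
expectancy stands in for the average remaining life years at the time
of health loss. Life expectancy at birth (not at the mean age of death
from the cause) is used throughout.

**3. Discounting.** The discounted variant annuitizes the half-life
span at annual rate *r* (default 3%):

    VSLY_disc,i = VSL_i / a(r, LE_i/2),   a(r, n) = (1 − (1+r)^−n) / r

with `a(0, n) = n` exactly, so the r = 0 case collapses to the plain
VSLY. Because `a(r, n) < n` for r > 0, discounting *raises* the
per-life-year value and hence the welfare loss; the uplift grows with
life expectancy (≈ +44% at LE 50 to ≈ +78% at LE 85 for r = 3%), which
is why aging, high-income populations show the largest discounted
increases. The annuity factor is evaluated in `expm1`/`log1p` form for
numerical stability as r → 0.

**4. Welfare loss and GDP share.**

    VLW_i = DALY_i × VSLY_i        %GDP_i = 100 × VLW_i / GDP_i

applied elementwise to the burden's central value and both ends of its
95% uncertainty interval. VSLY is treated as deterministic: only the
burden uncertainty propagates, so the interval ordering
(lower ≤ val ≤ upper) is preserved through every stage, exactly.

**Aggregation.** Regional figures (21 geographic regions, 7
super-regions, 5 SDI quintiles, global) sum member VLW triples
elementwise and compute the GDP share as the **ratio of sums**
`100 × Σ VLW_i / Σ GDP_i`, never the mean of member ratios. Every level
partitions the same country set, so totals are conserved across levels
to floating-point accumulation error. National summaries report the
across-country median and IQR; quartiles interpolate linearly between
order statistics (the numpy default) — the choice is immaterial at
n = 204 but is fixed for reproducibility. Rankings sort by the central
value, ties broken alphabetically. Regions that end up with zero
members (possible in small synthetic worlds) are omitted rather than
emitted as 0/0 percentages.

## Inputs and harmonization

Burden comes as a GBD-results-style CSV (Number metric, both sexes, all
ages; sex- or age-specific rows are ignored); both `*_name` and `*_id`
column dialects are accepted and the cause is matched case-insensitively
by substring. Rows violating lower ≤ val ≤ upper are rejected into a
report, never silently dropped. Economic inputs are WDI-style tables
(long or wide; WDI indicator codes or plain names). The location
universe is the canonical country list of the hierarchy table;
WDI-only aggregates ("World", "Euro area", …) are dropped with a report
line, and name variants are resolved through an alias table. The join
is order-independent and accounts for every input row: joined +
unmatched + flagged-for-imputation.

## Imputation

Missing economic cells are filled before valuation ever runs, in two
passes:

1. **Within-country time series**: linear interpolation between the
   nearest observed years; years outside the observed range carry the
   nearest observation flat (`numpy.interp` implements exactly this
   convention). Interpolation is exact for affine series.
2. **Whole-country gaps**: the population-weighted mean of observed
   countries in the same geographic region, cascading to the
   super-region and finally the global pool when fewer than three
   donors are available (the global fallback warns). For the population
   indicator itself a plain donor mean is used — weighting a population
   by itself would be self-referential. `gdp_total` is then closed as
   gdp_per_capita × population.

Every filled cell is listed in the imputation report (location,
indicator, year, method, value). Imputing a complete table is a no-op.
No model-based imputation (splines, multiple imputation, covariate
regression) is attempted.

## Synthetic worlds

`generate_world(WorldSpec(...))` emits burden, economic and hierarchy
files in the exact dialects the readers consume, plus a truth ledger of
every latent value and an independently computed expected VLW (one
closed-form expression at ε = 1, undiscounted, benchmark = the richest
generated country). Defaults, chosen once as round numbers a 2021
cross-country table would plausibly show:

| parameter | default | meaning |
| --- | --- | --- |
| `n_countries` | 204 | size of the country universe |
| `gdp_pc_lognormal` | (15 000 Int$, σ=1.1) | log-normal income spread |
| `population_lognormal` | (6 M, σ=1.9) | heavy-tailed population sizes |
| `le_link` | 40 + 3.2·ln(gdp_pc), clip [50, 88] | life expectancy rises with log income |
| `daly_rate_link` | 120/100k base, +0.8 per SDI step | burden rate rises with development |
| `ui_halfwidth` | 0.15 | relative 95%-interval half width |
| `missingness` | 0.05 | fraction of economic panel cells hidden |
| `volatility` | 0.02 | s.d. of year-over-year panel noise |

The income→life-expectancy and income→burden-rate links make the
qualitative gradient of real data (higher relative burden in richer,
older strata) emerge in synthetic worlds so that regional-ranking tests
are meaningful; the gradient strength is a parameter, not a claim. The
generator makes **no** attempt to match the actual 2021 distributions,
so passing tests demonstrate the arithmetic, plumbing and invariants of
the pipeline — not agreement with published burden figures, which
requires the real GBD and World Bank exports. Economic panels span
2017–2021 with smooth growth plus multiplicative noise; 2021 values are
the latents exactly, so a zero-missingness world closes the loop between
pipeline output and ledger prediction bit-for-bit. One seeded generator
drives all draws and files are written in canonical (location-sorted)
order, making output byte-identical for a fixed seed.

`make_toy3()` is the hand-checkable three-country fixture (incomes at
¼×, 1× and 2× the benchmark) whose companion truth table evaluates the
whole chain as direct arithmetic for every ε ∈ {0.55, 1.0, 1.5} ×
r ∈ {0, 0.03} combination.

## Numerical and design choices

- Floats are serialized in shortest round-trip form (and parsed with
  `float_precision="round_trip"`), so write→read→write cycles are
  byte-stable even for ~10¹² magnitudes where fixed decimal places
  exceed double precision.
- The GBD `val` column is the central estimate everywhere; draw-level
  uncertainty is not modelled.
- Scenario runs are pure functions of (inputs, parameters): any
  execution order gives identical bundles, and repeated runs write
  byte-identical CSVs.
- Degenerate inputs fail loudly: non-positive GDP or life expectancy,
  negative rates, empty selections and unresolvable or duplicated
  locations all raise typed errors rather than propagating NaNs.

## Problem sizes

Tests and the acceptance script run on the 3-country fixture, 204-country
synthetic worlds, and 1 000 randomized single-country evaluations against
an independent single-expression oracle; the full suite completes in a
few seconds on one CPU.

## Known limitations

- Half of life expectancy at birth is a crude stand-in for remaining
  life years; no age-at-death structure enters the discounting.
- The annuitized-VSLY discounting convention is one defensible choice
  among several; published analyses do not always state theirs, and
  uplift magnitudes depend on it.
- Benefit transfer with a single global ε ignores institutional and
  cultural heterogeneity in willingness to pay.
- The identity treatment of USD and PPP Int$ at the benchmark economy
  is an approximation; no deflator or market-exchange conversion is
  provided.
- Donor-based imputation assumes regional neighbours are informative
  for a country's missing indicator, which fails for outlier economies.
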