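# foodpolicy

Simulation toolkit for food tax and subsidy policies driven by a
conditional (Marshallian) price-elasticity matrix, with rescaling of total
food expenditure through a **total food expenditure elasticity (TFEe)**, and
a simplified downstream chain from diet change to BMI, potential impact
fractions and health-adjusted life years (HALYs).

## What it does

A conditional PE matrix assumes total food expenditure is unchanged by a
price change, but transplanting a matrix to a setting with different
consumption patterns silently breaks that assumption. The package
implements a two-step repair:

1. **Conditional step** — propagate policy price changes through the PE
   matrix, then rescale all quantity changes so total food expenditure is
   exactly unchanged.
2. **Expenditure step** — set the target expenditure change as
   `%ΔFPI × TFEe × X_B` (FPI = base-quantity-weighted food price index),
   allocate it across foods via per-food expenditure elasticities, and close
   with a scalar so the target is hit exactly.

A `conventional` mode applies the matrix raw (no rescaling) to expose the
implausible expenditure drifts the adjustment removes; `revealed_tfee`
diagnoses any run as the ratio of % expenditure change to % FPI change.

Additional components:

- `disaggregation` — expand an aggregated PE matrix (e.g. 23×23) to sub-food
  resolution (e.g. 345×345) using an own-PE strengthening scalar (central
  2.5% per sub-food, SD 1.25%) and share-proportional cross-PE allocation;
  row sums reproduce aggregate responses exactly.
- `tfee` — Beta(6,2) TFEe uncertainty distribution, conversion from an
  all-food own-PE (`1 + own_pe`), normal confidence intervals.
- `health` — steady-state energy→BMI conversion (94 kJ/day per kg),
  potential impact fractions, and a proportional multistate lifetable with
  annual cycles, lags and discounting.
- `uncertainty` — Monte-Carlo propagation (reproducible per-iteration
  substreams) and univariate sensitivity at the 2.5th/97.5th percentiles.
- `synthetic` — seeded generators for food systems, Cournot-consistent PE
  matrices, Engel-normalized expenditure-elasticity vectors, disaggregation
  schemes and toy health inputs.
- `datasets` — a bundled three-food demonstration of why transplanting a
  conditional matrix across settings distorts totals.

## CLI

```sh
# write a synthetic fixture bundle (foods/PE/EE/scheme/policy)
foodpolicy make-fixtures --n-groups 5 --seed 1 --out-dir fixtures/

# run one policy scenario
foodpolicy run-scenario --foods fixtures/foods.csv --pe fixtures/pe.csv \
    --ee fixtures/ee.csv --policy fixtures/policy.yaml \
    --tfee 0.75 --mode tfee_adjusted --out result.json

# Monte-Carlo uncertainty (one CSV row per iteration)
foodpolicy run-uncertainty --foods fixtures/foods.csv --pe fixtures/pe.csv \
    --ee fixtures/ee.csv --policy fixtures/policy.yaml \
    --iters 2000 --seed 1234 --out draws.csv --summary-out summary.json

# univariate sensitivity, expand a PE matrix
foodpolicy univariate ... --param tfee --out uni.json
foodpolicy disaggregate --pe pe.csv --scheme scheme.csv --out fine.csv
```

File formats: foods as CSV (`food_id, group_id, price_per_100g,
grams_per_day, kj_per_100g` + one column per nutrient in g/100 g), PE matrix
as square CSV with food-id headers, EE vector as two-column CSV, policy as
YAML (`nutrient_taxes`, `ad_valorem`, `name`). Prices are per 100 g,
quantities g/day; percent values are serialized as percents with a units
tag, while the internal representation is fractional.

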