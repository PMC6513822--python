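# spendsim

Small-area estimates of weekly household expenditure by **spatial
microsimulation**: survey microdata (individuals with socio-demographic
attributes and an expenditure diary) are reweighted by **iterative
proportional fitting (IPF)** to zone-level constraint tables, producing a
per-zone, per-commodity estimate of average weekly expenditure in £ per
person. The approach targets the gap between individual-level expenditure
surveys (geocoded only to 12 broad regions) and the local-authority scale
at which public-health, retail and environmental questions are actually
asked — e.g. where tobacco, alcohol or fresh-vegetable spending
concentrates.

## Who this is for

Quantitative geographers, public-health and retail analysts who have
(a) individual survey microdata with categorical attributes and spending
records, and (b) per-zone marginal tables (census/labour-market counts)
for those same attributes. Because the real UK inputs (the Living Costs
and Food Survey, census and labour-market tables) are licensed, the
package ships a **synthetic-data generator** that emulates their joint
statistical structure with a known ground truth, so the entire pipeline is
runnable and testable out of the box.

## The model

Let *i* index survey individuals and *z* zones. IPF maintains a
nonnegative weight matrix *w(i, z)* (initialised at 1; no geographic
restriction on which individual may serve which zone) and cycles through
the constraint variables *c* with per-zone targets *T_c(z, k)* over
categories *k*, applying the multiplicative update

    w(i, z) ← w(i, z) · T_c(z, k(i)) / Σ_{j : k(j) = k(i)} w(j, z)

After each update the simulated marginal of *c* matches its target
exactly; at convergence all constraints agree simultaneously, monitored by
the total absolute error (TAE) per zone relative to the zone baseline.

Around this core:

- **Baseline**: mid-year population minus communal-establishment
  residents = household residents per zone; every other constraint is
  rescaled to it. Adults (16+) and children (≤15) are fitted as separate
  models and merged.
- **Constraints**: age–sex (12 adult bands), household type (17 classes),
  ethnicity (4), student and unemployment status, and income — eight
  published wage percentiles per zone turned into 8 equal employee deciles
  + a double-width top bracket + self-employed/other. Income
  categorisation of the microdata is *zone-specific*: each zone's own
  bracket boundaries re-classify every individual.
- **Missing data**: zones lacking a binary constraint drop it; partially
  missing ethnicity categories are folded into the catch-all and the
  microdata relabelled identically for that zone; the model runs on
  age–sex + household type as a minimum.
- **Prices**: diary amounts are deflated from the respondent's region to a
  UK-average level and reflated to the destination zone's region using
  relative regional consumer price level (RRCPL) indices, per price
  category (food, alcohol/tobacco, catering).
- **Validation**: per-zone correlation between constraint targets and
  fitted marginals (internal); population-weighted regional means vs
  survey means ± 1.96 SE, and Spearman rank correlation against a
  deprivation-style zone ranking (external).

## Worked example

```python
from spendsim import ExpenditureMicrosimulation
from spendsim.synthetic_data import generate_world

world = generate_world(seed=1)          # 30 zones, 6000 survey individuals
model = ExpenditureMicrosimulation.from_world(world)
res = model.fit(tol=1e-4, max_iter=50)
print(res.summary())
```

```
Expenditure microsimulation results
===================================
adult individuals:      4984
child individuals:      1016
zones:                  30
constraints fitted:     age_sex, household_type, ethnicity, student, unemployment, income
sweeps:                 29
converged:              True
max zone rel. TAE:      9.496e-05
empty cells dropped:    0
internal r (min/med):   1.000000 / 1.000000
total population:       87,094
```

The fit converged in 29 sweeps; every zone's constraint targets are
reproduced to correlation 1 (six decimals). Estimates and validation hang
off the results object:

```python
est = res.expenditure()                         # zone x commodity, £/person/week
print(est["2.2.1.1.1"].round(2).head(3))        # cigarettes
# E09000001    1.01
# E09000002    1.00
# E09000003    1.00
ranks = world.deprivation.set_index("zone_code")["rank"]
print(res.rank_correlation(ranks).round(3))
#                     label    rho  p_value   n
#        all_food_and_drink  0.798      0.0  30
#          alcoholic_drinks  0.651      0.0  30
#    tobacco_and_cigarettes -0.915      0.0  30
```

Food spending rank-correlates positively with the (low = deprived)
ranking and tobacco negatively — the expected deprivation signature.
Against the generator's ground truth, pooled zone × category recovery is
r ≈ 0.999.

The same pipeline is scriptable from a shell:

```bash
spendsim simulate --out world/ --zones 30 --seed 1
spendsim fit      --world world/ --out run/
spendsim estimate --world world/ --run run/ --out run/
spendsim validate --world world/ --run run/ --out run/
```

## Layout

- `src/spendsim/synthetic_data.py` — ground-truth world generator
- `src/spendsim/microdata_prep.py` — survey categorisation, calendar-year alignment
- `src/spendsim/constraints.py` — baselines, scaling, income brackets, harmonisation
- `src/spendsim/ipf.py` — the reweighting core and child-model closed form
- `src/spendsim/prices.py` — regional price adjustment
- `src/spendsim/estimates.py` — weighted totals, merging, COICOP aggregation
- `src/spendsim/validation.py` — internal/external validation
- `src/spendsim/model.py` — the Model/Results interface
- `src/spendsim/cli.py` — `spendsim` command-line driver
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
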