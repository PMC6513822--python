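# Methods

This note records the modelling assumptions, parameter choices and known
limitations of spendsim. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The reweighting model

Spatial microsimulation here means deterministic survey reweighting: a
weight matrix *w(i, z)* over survey individuals *i* and zones *z*, fitted
by iterative proportional fitting (IPF). Each constraint variable *c*
partitions individuals into categories with per-zone target counts
*T_c(z, ·)*; the update multiplies the weights of category *k*'s members
in zone *z* by `T_c(z, k) / simulated_c(z, k)`. Properties relied on and
tested:

- immediately after updating on *c*, the simulated marginal of *c*
  equals its target to machine precision;
- the total absolute error (TAE) summed over constraints is nonincreasing
  between full sweeps on feasible systems;
- the fixed point is independent of update order, but the iterate path is
  not, so the order is fixed (age_sex, household_type, ethnicity, student,
  unemployment, income) and configurable.

Initial weights are 1 for every (individual, zone) pair; no geographic
restriction links an individual's home region to the zones it may serve
(restricting the pool by region would leave too few donors per region).
Weights remain fractional throughout — targets are real-valued (scaled
constraints are fractional by construction) and the estimand is a mean,
so integerisation would only add error.

**Convergence** is declared when max over constraints and zones of
TAE(zone)/baseline(zone) < `tol` (default 1e-4), or abandoned after
`max_iter` = 50 sweeps with `converged=False`. The criterion is a
normalised L1 distance, so `tol` is unit-free.

**Empty cells** (positive target, zero microdata mass) are resolved before
iterating: the default drops the category from that zone's target and
rescales the remaining categories to the baseline, logging each cell;
`strict` mode raises instead. Categories with microdata mass but zero
target simply receive zero weight in that zone.

**Adult/child split.** Individuals aged 16+ enter the full six-constraint
model; those 15 and under enter a single-constraint model over four
age–sex bands, which converges in one sweep with the closed form
`w(i, z) = T(z, k(i)) / n_micro(k(i))` (tested against the iterated fit).
The 17 household-type labels apply to the adult pool only.

## Constraint construction

- **Baseline**: mid-year zone population minus communal-establishment
  residents, per age–sex cell. Communal counts are observed once (census
  year) and held constant across years — communal populations are small
  (~2%) and demographically stable. Negative cells (inconsistent sources)
  clamp to zero with a warning.
- **Scaling**: every other constraint's zone row is multiplied by
  baseline/rowsum, preserving category proportions exactly. This is
  idempotent and invariant to positive rescaling of the raw counts.
  Communal subtraction is applied only to age–sex; the other sources
  already exclude most communal residents.
- **Income**: published P10..P80 gross-weekly-pay boundaries per zone plus
  employee/self-employed/other headcounts become eleven categories: eight
  employee deciles of employees/10 each, a P80–P100 bracket of
  employees/5, and the two non-employee types. Microdata categorisation is
  zone-specific: each zone's boundaries re-bracket every individual's
  wage (non-employees are categorised by employment type, wage ignored).
  A missing boundary merges the two brackets it separates; the merged
  bracket keeps the label of its lowest constituent decile, which is
  exactly the label `searchsorted` over the surviving boundaries assigns,
  so targets and categorisation stay consistent. This merge rule is a
  design choice; the alternative (dropping income for such zones) is
  available by declaring the zone unavailable in the manifest.
- **Missing variables**: availability is declared in a per-zone manifest
  (or inferred from NaN patterns). Binary constraints drop per zone;
  partially missing ethnicity categories fold into the `other` catch-all
  with the microdata relabelled identically for that zone (implemented as
  zone-specific category codes in the IPF). Age–sex and household type
  are mandatory everywhere; the model runs on those two as a minimum. An
  `audit` command reports zones-per-variable-per-year counts.

## Price adjustment

Regional price indices (UK = 100) exist in two vintages, 2010 and 2016;
years 2008–2012 use the former, 2013 onwards the latter. Detailed
per-category indices exist for London, Scotland, Wales and Northern
Ireland; other regions carry one aggregate index repeated across the three
price categories (food & non-alcoholic drinks, alcohol & tobacco,
catering). Adjustment is the exact ratio `idx_dest / idx_source`, applied
per diary record; it preserves zero, is positively homogeneous and
multiplicative over intermediate regions. Northern Ireland individuals may
appear in the survey pool (source side) but never as a destination. The
2016 index table ships with its published values; the 2010 table is a
synthetic stand-in with the same layout (see the file name), which only
matters if estimates for 2008–2012 are interpreted against real data.
No temporal deflation is applied — estimates are in current prices of
their year.

## Estimates

Zone totals are `W.T @ E` with E the individuals × commodities diary
matrix deflated to UK-average prices, reflated by destination region.
Adult and child totals merge and divide by the combined household
population: the output unit is £ per person (all residents) per week. A
child diary is accepted but defaults to absent (children's recorded
spending is negligible in the source survey); children then contribute
population only. Commodity aggregation is exact summation over a code
list or a dot-hierarchy prefix, and the 80-category scheme collapses the
away-from-home codes to their aggregates (the reduced reporting used from
2016 onwards).

## The synthetic world

The generator emulates the licensed inputs' statistical structure:

- **Zones** (default 30, ~2,500 adults and ~500 children each) sit on an
  affluence gradient that moves unemployment (2–12%, the range across
  real districts), employment mix, wage location, demography and
  household composition; independent gradients move student share,
  ethnic composition and age structure so the constraints are not
  collinear. Children track the adult population (ratio × U(0.85, 1.15))
  because dependent-child shares vary far less between districts than
  totals do.
- **Attributes** are drawn per person from the zone's categorical
  distributions; household type is drawn conditional on age band from the
  labels an adult of that age can carry; the unemployed cannot be current
  employees. Employee wages are lognormal with zone-specific location
  (median ≈ £330–£540) and σ = 0.55; percentile boundaries are type-7
  (linear interpolation) quantiles, fixed so the sort-based oracle in the
  tests is exact.
- **Expenditure** is log-linear: `log E = log(baseline) + Σ effects +
  σ·N(0,1)`, times a Bernoulli purchase indicator (participation 0.22 for
  cigarettes, 0.45 for spirits, 0.8 for restaurant meals, 0.95
  otherwise). Effect sizes encode the documented socio-economic
  gradients: tobacco rises with unemployment (+0.9 log units) and falls
  with employment; food, fruit/vegetables and eating out do the reverse
  (±0.2–0.8). Eight commodity codes span the three price categories.
- **Survey**: 6,000 persons sampled without replacement across zones; the
  zone label is dropped (only region retained), mirroring the real
  survey's coarse geocoding; diary amounts are expressed at the
  respondent's regional price level and zero records omitted.
- **Ground truth**: realized per-person zone means at the zone's regional
  price level, plus the exact population cross-tabulations behind every
  constraint (conservation is asserted in the tests). A deprivation-like
  ranking (rank 1 = highest unemployment) supports the directional
  external-validation check.

What the generator does **not** emulate: household-level clustering of
diaries, spatial autocorrelation between zones, seasonal variation,
non-response bias, and measurement error in self-reported spending.
Passing tests therefore demonstrate that the pipeline recovers structure
of this kind when it exists; they do not certify accuracy against the
biases of real survey data.

## Problem sizes and numerical choices

The tests and the acceptance script run the full pipeline at 30 zones ×
6,000 survey individuals (the smaller unit-test world uses 5 zones ×
~900), sizes chosen so the complete suite runs in seconds while keeping
≥10 microdata donors per attribute category (the generator enforces
`survey_size ≥ 10 ×` the number of distinct categories, guarding against
the thin-donor-pool failure mode). Quantiles are linear-interpolation
(type 7) everywhere; Pearson correlations with a zero-variance vector are
reported as undefined (NaN), never 1; Spearman uses average ranks on ties
with the two-sided t-approximation p-value. Seeded runs are
bit-reproducible; derived seeds offset the base seed by fixed small
constants for the communal draw and the survey draw.

## Limitations

- IPF matches marginals only: cross-tabulations between constrained
  variables are inherited from the survey pool, not fitted, and the
  target variable's zone variation is recovered only insofar as it is
  driven by constrained attributes.
- No uncertainty intervals accompany the zone estimates (the method is
  deterministic given its inputs); external comparison uses the survey
  side's sampling error only.
- The shipped commodity list and the 2010 price table are synthetic
  stand-ins; analyses of real data must substitute the licensed
  originals, for which the readers/loaders accept the same layouts.
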