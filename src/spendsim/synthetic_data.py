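"""Synthetic ground-truth world for end-to-end pipeline testing.

The real inputs to the expenditure microsimulation — the household
expenditure survey microdata, the census and labour-market constraint
tables, the published wage percentiles — are licensed and cannot be
redistributed.  This module generates a self-contained stand-in world with
the statistical structure the analysis assumes, so every downstream stage
is testable without a download:

* a true population of adults and children allocated to zones, each person
  carrying the full set of categorical attributes and a latent weekly
  expenditure per commodity category (log-linear in the attributes with
  lognormal noise, times a Bernoulli purchase indicator for sparse
  categories such as tobacco);
* a survey sample drawn from that population with the zone label dropped
  (only the region is retained, mirroring the coarse geocoding of the real
  survey) and a purchase diary priced at the respondent's regional level;
* per-zone constraint tables tabulated exactly from the true population,
  plus wage percentile boundaries in the published layout;
* the ground truth the pipeline should recover: the per-person mean weekly
  expenditure per zone and category.

Zone-to-zone variation is driven by an affluence gradient that shifts
unemployment, employment mix, demography and wages, so that estimated and
true zone expenditure differ between zones in a recoverable way, and a
deprivation-like zone ranking can be emitted for directional external
validation (food positively, tobacco negatively rank-correlated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    AGE_SEX_ADULT,
    AGE_SEX_CHILD,
    EMPLOYMENT_TYPE,
    ETHNICITY,
    GB_REGIONS,
    HOUSEHOLD_BY_AGE_BAND,
    HOUSEHOLD_TYPES,
    STUDENT,
    UNEMPLOYMENT,
    load_coicop_lookup,
)
from .constraints import PERCENTILE_COLUMNS, ConstraintTable
from .prices import RRCPLTable, price_category, select_vintage

logger = logging.getLogger(__name__)

_N_DISTINCT_CATEGORIES = (
    len(AGE_SEX_ADULT)
    + len(AGE_SEX_CHILD)
    + len(ETHNICITY)
    + len(STUDENT)
    + len(UNEMPLOYMENT)
    + len(EMPLOYMENT_TYPE)
    + len(HOUSEHOLD_TYPES)
)


@dataclass
class ExpenditureModelSpec:
    """Log-linear attribute model for latent weekly expenditure.

    For person i and category c:
        log E_ic = log(baseline[c]) + sum of effects[c][(var, attr_iv)]
                   + sigma[c] * N(0, 1)
    and the recorded amount is ``E_ic`` times a Bernoulli(participation[c])
    purchase indicator (tobacco, for instance, is bought by a minority).
    Amounts are expressed at UK-average prices; regional price factors are
    applied when the survey diary is emitted.
    """

    categories: list[str]
    baseline: dict[str, float]
    effects: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    participation: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for c in self.categories:
            if self.baseline.get(c, -1) < 0:
                raise ValueError(f"baseline missing or negative for {c}")
            if not 0 <= self.participation.get(c, 1.0) <= 1:
                raise ValueError(f"participation out of [0,1] for {c}")
            if self.sigma.get(c, 0.0) < 0:
                raise ValueError(f"negative noise scale for {c}")


@dataclass
class WorldConfig:
    """Full specification of a synthetic world.

    ``attribute_distributions`` maps variable name to a zone x category
    probability table (each row sums to 1); ``household_conditional`` holds,
    per adult age band, a zone x allowed-household-type probability table.
    ``wage_location`` is the per-zone log-scale location of the employee
    wage lognormal.
    """

    n_zones: int
    adult_populations: np.ndarray
    child_populations: np.ndarray
    region_of_zone: list[str]
    attribute_distributions: dict[str, pd.DataFrame]
    household_conditional: dict[str, pd.DataFrame]
    wage_location: np.ndarray
    wage_sigma: float
    expenditure_model: ExpenditureModelSpec
    survey_size: int
    seed: int
    year: int = 2013
    apply_regional_prices: bool = True
    communal_rate: float = 0.015

    @property
    def zone_codes(self) -> pd.Index:
        return pd.Index(
            [f"E09{z + 1:06d}" for z in range(self.n_zones)], name="zone_code"
        )

    def validate(self) -> None:
        if self.n_zones < 1:
            raise ValueError("need at least one zone")
        if (np.asarray(self.adult_populations) <= 0).any() or (
            np.asarray(self.child_populations) <= 0
        ).any():
            raise ValueError("zone populations must be positive")
        if len(self.region_of_zone) != self.n_zones:
            raise ValueError("region_of_zone length != n_zones")
        for var, probs in self.attribute_distributions.items():
            rowsums = probs.sum(axis=1)
            off = (rowsums - 1.0).abs() > 1e-9
            if off.any():
                raise ValueError(
                    f"distribution for {var!r} does not sum to 1 in zone(s) "
                    f"{list(probs.index[off])}"
                )
            if (probs.to_numpy() < 0).any():
                raise ValueError(f"negative probabilities for {var!r}")
        for band, probs in self.household_conditional.items():
            off = (probs.sum(axis=1) - 1.0).abs() > 1e-9
            if off.any():
                raise ValueError(f"household conditional for band {band} not normalised")
        min_pool = 10 * _N_DISTINCT_CATEGORIES
        if self.survey_size < min_pool:
            raise ValueError(
                f"survey_size {self.survey_size} below sampling-pool floor "
                f"{min_pool} (10 x number of distinct attribute categories)"
            )
        self.expenditure_model.validate()


def default_expenditure_model() -> ExpenditureModelSpec:
    """Eight-category default spanning the three price categories.

    Baselines are weekly pounds per purchasing adult; effect sizes are
    log-additive.  Tobacco spending rises with unemployment while food,
    fruit/vegetables and eating out fall — the deprivation-linked pattern
    the external validation checks directionally.
    """
    categories = [
        "1.1.1.4.1",   # cakes and puddings
        "1.1.2.5.2",   # bacon and ham
        "1.1.6.2.1",   # bananas
        "1.1.7.1.4",   # other fresh vegetables
        "1.2.1.1.1",   # coffee
        "2.1.1.1.1",   # spirits (brought home)
        "2.2.1.1.1",   # cigarettes
        "11.1.1.1.1",  # restaurant meals
    ]
    baseline = {
        "1.1.1.4.1": 2.4,
        "1.1.2.5.2": 1.9,
        "1.1.6.2.1": 1.1,
        "1.1.7.1.4": 3.2,
        "1.2.1.1.1": 1.6,
        "2.1.1.1.1": 3.8,
        "2.2.1.1.1": 4.5,
        "11.1.1.1.1": 7.5,
    }
    effects = {
        "1.1.1.4.1": {
            ("student", "student"): 0.10,
            ("unemployment", "unemployed"): -0.30,
            ("employment_type", "Employee"): 0.20,
        },
        "1.1.2.5.2": {
            ("unemployment", "unemployed"): -0.35,
            ("employment_type", "Employee"): 0.25,
        },
        "1.1.6.2.1": {
            ("unemployment", "unemployed"): -0.50,
            ("employment_type", "Employee"): 0.30,
        },
        "1.1.7.1.4": {
            ("unemployment", "unemployed"): -0.50,
            ("employment_type", "Employee"): 0.35,
            ("age_sex", "F_65_74"): 0.10,
            ("age_sex", "M_65_74"): 0.10,
        },
        "1.2.1.1.1": {("employment_type", "Employee"): 0.30},
        "2.1.1.1.1": {
            ("unemployment", "unemployed"): -0.30,
            ("employment_type", "Employee"): 0.20,
        },
        "2.2.1.1.1": {
            ("unemployment", "unemployed"): 0.90,
            ("employment_type", "Employee"): -0.25,
            ("student", "student"): -0.30,
            ("age_sex", "F_75_pl"): -0.60,
            ("age_sex", "M_75_pl"): -0.60,
        },
        "11.1.1.1.1": {
            ("unemployment", "unemployed"): -0.80,
            ("employment_type", "Employee"): 0.40,
            ("student", "student"): 0.25,
            ("age_sex", "F_16_24"): 0.30,
            ("age_sex", "M_16_24"): 0.30,
        },
    }
    sigma = {c: 0.6 for c in categories}
    participation = {c: 0.95 for c in categories}
    participation["2.2.1.1.1"] = 0.22
    participation["2.1.1.1.1"] = 0.45
    participation["11.1.1.1.1"] = 0.80
    return ExpenditureModelSpec(categories, baseline, effects, sigma, participation)


def default_config(
    n_zones: int = 30,
    mean_adults: int = 2500,
    mean_children: int = 500,
    survey_size: int = 6000,
    seed: int = 0,
    year: int = 2013,
) -> WorldConfig:
    """Standard study conditions: zone-varying attribute mixes on an
    affluence gradient, lognormal wages, the default expenditure model."""
    rng = np.random.default_rng(seed)
    zone_codes = pd.Index([f"E09{z + 1:06d}" for z in range(n_zones)], name="zone_code")

    affluence = np.linspace(-1.0, 1.0, n_zones)
    g_student = rng.permutation(np.linspace(-1.0, 1.0, n_zones))
    g_diverse = rng.permutation(np.linspace(-1.0, 1.0, n_zones))
    g_age = rng.permutation(np.linspace(-1.0, 1.0, n_zones))
    g_dep = rng.permutation(np.linspace(-1.0, 1.0, n_zones))

    adult_pops = rng.integers(
        int(mean_adults * 0.6), int(mean_adults * 1.4) + 1, size=n_zones
    )
    # children track the adult population (dependent-child shares vary far
    # less between districts than total populations do)
    child_ratio = mean_children / mean_adults
    child_pops = np.maximum(
        1,
        np.round(
            adult_pops * child_ratio * rng.uniform(0.85, 1.15, size=n_zones)
        ).astype(int),
    )
    regions = [GB_REGIONS[z % len(GB_REGIONS)] for z in range(n_zones)]

    dists: dict[str, pd.DataFrame] = {}

    p_unemp = 0.07 - 0.05 * affluence
    dists["unemployment"] = pd.DataFrame(
        {"unemployed": p_unemp, "not_unemployed": 1 - p_unemp}, index=zone_codes
    )[UNEMPLOYMENT]

    p_stud = 0.10 + 0.05 * g_student
    dists["student"] = pd.DataFrame(
        {"student": p_stud, "not_student": 1 - p_stud}, index=zone_codes
    )[STUDENT]

    p_white = 0.88 - 0.10 * (g_diverse + 1) / 2
    rest = 1 - p_white
    dists["ethnicity"] = pd.DataFrame(
        {
            "white": p_white,
            "mixed": 0.12 * rest,
            "black": 0.33 * rest,
            "other": 0.55 * rest,
        },
        index=zone_codes,
    )[ETHNICITY]

    p_emp = 0.62 + 0.08 * affluence
    p_self = 0.10 + 0.02 * affluence
    dists["employment_type"] = pd.DataFrame(
        {"Employee": p_emp, "Self-employed": p_self, "Other": 1 - p_emp - p_self},
        index=zone_codes,
    )[EMPLOYMENT_TYPE]

    # adult age-sex: a base profile tilted young/old by g_age
    base = np.array([0.075, 0.085, 0.125, 0.115, 0.055, 0.045] * 2)
    tilt = np.array([1.0, 0.5, 0.0, -0.3, -0.6, -1.0] * 2)
    mat = base[None, :] * (1 + 0.25 * g_age[:, None] * tilt[None, :])
    mat /= mat.sum(axis=1, keepdims=True)
    dists["age_sex"] = pd.DataFrame(mat, index=zone_codes, columns=AGE_SEX_ADULT)

    child_base = np.array([0.27, 0.23, 0.27, 0.23])
    dists["age_sex_child"] = pd.DataFrame(
        np.tile(child_base, (n_zones, 1)), index=zone_codes, columns=AGE_SEX_CHILD
    )

    household_conditional: dict[str, pd.DataFrame] = {}
    for band, allowed in HOUSEHOLD_BY_AGE_BAND.items():
        k = len(allowed)
        w = np.ones((n_zones, k))
        for j, label in enumerate(allowed):
            if "dep_y" in label:
                w[:, j] *= 1 + 0.4 * g_dep
            if label.endswith("_sph"):
                w[:, j] *= 0.6
        w /= w.sum(axis=1, keepdims=True)
        household_conditional[band] = pd.DataFrame(
            w, index=zone_codes, columns=allowed
        )

    wage_location = np.log(420.0) + 0.25 * affluence

    return WorldConfig(
        n_zones=n_zones,
        adult_populations=adult_pops,
        child_populations=child_pops,
        region_of_zone=regions,
        attribute_distributions=dists,
        household_conditional=household_conditional,
        wage_location=wage_location,
        wage_sigma=0.55,
        expenditure_model=default_expenditure_model(),
        survey_size=survey_size,
        seed=seed,
        year=year,
    )


@dataclass
class GroundTruth:
    """Recovery targets: what the pipeline should reproduce."""

    true_zone_expenditure: pd.DataFrame  # zone x category, pounds/person/week
    true_population_tables: dict[str, pd.DataFrame]  # zone x category counts


def _draw_categorical(
    rng: np.random.Generator, probs: np.ndarray, size: int
) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right")


def generate_population(
    config: WorldConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full true population, one record per person.

    Deterministic given ``config.seed``.  Adults carry all constraint
    attributes plus a latent weekly expenditure per category (UK-average
    prices); children carry the four child age-sex bands and spend nothing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    zone_codes = config.zone_codes
    model = config.expenditure_model

    frames = []
    for z, zone in enumerate(zone_codes):
        n_a = int(config.adult_populations[z])
        n_c = int(config.child_populations[z])

        age_idx = _draw_categorical(
            rng, config.attribute_distributions["age_sex"].iloc[z].to_numpy(), n_a
        )
        age_sex = np.array(AGE_SEX_ADULT, dtype=object)[age_idx]
        eth = np.array(ETHNICITY, dtype=object)[
            _draw_categorical(
                rng, config.attribute_distributions["ethnicity"].iloc[z].to_numpy(), n_a
            )
        ]
        stud = np.array(STUDENT, dtype=object)[
            _draw_categorical(
                rng, config.attribute_distributions["student"].iloc[z].to_numpy(), n_a
            )
        ]
        unemp = np.array(UNEMPLOYMENT, dtype=object)[
            _draw_categorical(
                rng,
                config.attribute_distributions["unemployment"].iloc[z].to_numpy(),
                n_a,
            )
        ]
        emp = np.array(EMPLOYMENT_TYPE, dtype=object)[
            _draw_categorical(
                rng,
                config.attribute_distributions["employment_type"].iloc[z].to_numpy(),
                n_a,
            )
        ]
        # an unemployed person cannot be a current employee
        emp = np.where(unemp == "unemployed", "Other", emp)

        hh = np.empty(n_a, dtype=object)
        for band, table in config.household_conditional.items():
            mask = np.char.endswith(age_sex.astype(str), band)
            k = int(mask.sum())
            if k:
                idx = _draw_categorical(rng, table.iloc[z].to_numpy(), k)
                hh[mask] = np.array(table.columns, dtype=object)[idx]

        wage = np.zeros(n_a)
        is_emp = emp == "Employee"
        wage[is_emp] = rng.lognormal(
            mean=config.wage_location[z], sigma=config.wage_sigma, size=int(is_emp.sum())
        )

        adult = pd.DataFrame(
            {
                "zone_code": zone,
                "region": config.region_of_zone[z],
                "is_adult": True,
                "age_sex": age_sex,
                "ethnicity": eth,
                "student": stud,
                "unemployment": unemp,
                "employment_type": emp,
                "gross_weekly_wage": np.round(wage, 2),
                "household_type": hh,
            }
        )
        for code in model.categories:
            log_amt = np.full(n_a, np.log(model.baseline[code]))
            for (var, cat), eff in model.effects.get(code, {}).items():
                log_amt += eff * (adult[var].to_numpy() == cat)
            s = model.sigma.get(code, 0.0)
            if s > 0:
                log_amt = log_amt + s * rng.standard_normal(n_a)
            amt = np.exp(log_amt)
            p = model.participation.get(code, 1.0)
            if p < 1.0:
                amt = amt * (rng.random(n_a) < p)
            adult[f"exp_{code}"] = amt

        cage = np.array(AGE_SEX_CHILD, dtype=object)[
            _draw_categorical(
                rng,
                config.attribute_distributions["age_sex_child"].iloc[z].to_numpy(),
                n_c,
            )
        ]
        child = pd.DataFrame(
            {
                "zone_code": zone,
                "region": config.region_of_zone[z],
                "is_adult": False,
                "age_sex": cage,
                "ethnicity": "white",
                "student": "not_student",
                "unemployment": "not_unemployed",
                "employment_type": "Other",
                "gross_weekly_wage": 0.0,
                "household_type": "child",
            }
        )
        for code in model.categories:
            child[f"exp_{code}"] = 0.0
        frames.append(adult)
        frames.append(child)

    population = pd.concat(frames, ignore_index=True)
    population.insert(0, "person_id", np.arange(1, len(population) + 1))

    truth = _ground_truth(population, config)
    return population, truth


def _ground_truth(population: pd.DataFrame, config: WorldConfig) -> GroundTruth:
    model = config.expenditure_model
    exp_cols = [f"exp_{c}" for c in model.categories]
    totals = population.groupby("zone_code")[exp_cols].sum()
    persons = population.groupby("zone_code").size()
    per_person = totals.div(persons, axis=0)
    per_person.columns = model.categories

    if config.apply_regional_prices:
        rrcpl = select_vintage(config.year)
        lookup = load_coicop_lookup()
        region_of = dict(zip(config.zone_codes, config.region_of_zone))
        for code in model.categories:
            pc = price_category(code, lookup)
            factors = np.array(
                [rrcpl.index(region_of[z], pc) / 100.0 for z in per_person.index]
            )
            per_person[code] = per_person[code] * factors

    tables = {
        "age_sex": _tab(population[population["is_adult"]], "age_sex", AGE_SEX_ADULT),
        "age_sex_child": _tab(
            population[~population["is_adult"]], "age_sex", AGE_SEX_CHILD
        ),
        "ethnicity": _tab(population[population["is_adult"]], "ethnicity", ETHNICITY),
        "student": _tab(population[population["is_adult"]], "student", STUDENT),
        "unemployment": _tab(
            population[population["is_adult"]], "unemployment", UNEMPLOYMENT
        ),
        "household_type": _tab(
            population[population["is_adult"]], "household_type", HOUSEHOLD_TYPES
        ),
    }
    return GroundTruth(per_person, tables)


def _tab(df: pd.DataFrame, var: str, categories: list[str]) -> pd.DataFrame:
    out = (
        df.groupby(["zone_code", var]).size().unstack(fill_value=0)
    )
    return out.reindex(columns=categories, fill_value=0).astype(float)


@dataclass
class ConstraintBundle:
    """Everything the constraints stage consumes, in published layouts."""

    raw: dict[str, ConstraintTable]
    child_age_sex: ConstraintTable
    earnings: pd.DataFrame  # zone_code, p10..p80, employees, self_employed, other
    midyear_adult: pd.DataFrame
    communal_adult: pd.DataFrame
    midyear_child: pd.DataFrame
    communal_child: pd.DataFrame


def tabulate_constraints(
    population: pd.DataFrame, config: WorldConfig
) -> ConstraintBundle:
    """Tabulate per-zone marginal tables exactly from the true population.

    Also fabricates the census-style inputs to baseline construction: a
    small communal-establishment population is drawn per cell and added to
    the household counts to form the mid-year estimates, so that
    subtracting communal residents recovers the household baseline exactly.
    Wage percentile boundaries are linear-interpolation (type-7) quantiles
    of the zone's employee wages.
    """
    adults = population[population["is_adult"]]
    raw = {
        "age_sex": ConstraintTable("age_sex", _tab(adults, "age_sex", AGE_SEX_ADULT)),
        "household_type": ConstraintTable(
            "household_type", _tab(adults, "household_type", HOUSEHOLD_TYPES)
        ),
        "ethnicity": ConstraintTable("ethnicity", _tab(adults, "ethnicity", ETHNICITY)),
        "student": ConstraintTable("student", _tab(adults, "student", STUDENT)),
        "unemployment": ConstraintTable(
            "unemployment", _tab(adults, "unemployment", UNEMPLOYMENT)
        ),
    }
    children = population[~population["is_adult"]]
    child_ct = ConstraintTable(
        "age_sex_child", _tab(children, "age_sex", AGE_SEX_CHILD)
    )

    rows = []
    for zone, grp in adults.groupby("zone_code"):
        emp_wages = grp.loc[
            grp["employment_type"] == "Employee", "gross_weekly_wage"
        ].to_numpy()
        if emp_wages.size:
            bounds = np.quantile(emp_wages, np.arange(0.1, 0.81, 0.1))
        else:
            bounds = np.full(8, np.nan)
        rows.append(
            {
                "zone_code": zone,
                **dict(zip(PERCENTILE_COLUMNS, bounds)),
                "employees": int((grp["employment_type"] == "Employee").sum()),
                "self_employed": int((grp["employment_type"] == "Self-employed").sum()),
                "other": int((grp["employment_type"] == "Other").sum()),
            }
        )
    earnings = pd.DataFrame(rows)

    # census-style inputs: midyear = household + communal, communal fixed
    rng = np.random.default_rng(config.seed + 1)
    comm_a = pd.DataFrame(
        rng.poisson(config.communal_rate * raw["age_sex"].counts.to_numpy()),
        index=raw["age_sex"].counts.index,
        columns=raw["age_sex"].counts.columns,
    ).astype(float)
    comm_c = pd.DataFrame(
        rng.poisson(config.communal_rate * child_ct.counts.to_numpy()),
        index=child_ct.counts.index,
        columns=child_ct.counts.columns,
    ).astype(float)
    return ConstraintBundle(
        raw=raw,
        child_age_sex=child_ct,
        earnings=earnings,
        midyear_adult=raw["age_sex"].counts + comm_a,
        communal_adult=comm_a,
        midyear_child=child_ct.counts + comm_c,
        communal_child=comm_c,
    )


def sample_survey(
    population: pd.DataFrame, config: WorldConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the survey: microdata without the zone label, plus the diary.

    ``survey_size`` persons are sampled without replacement across all
    zones.  The emitted microdata keeps only the region — the zone is
    deliberately dropped, as in the real survey's coarse geocoding.  Diary
    amounts are the sampled adults' latent expenditures re-expressed at
    their own region's price level (when ``apply_regional_prices``); zero
    amounts are omitted, mirroring diary sparsity.
    """
    if config.survey_size > len(population):
        raise ValueError("survey_size exceeds population size")
    rng = np.random.default_rng(config.seed + 2)
    pick = rng.choice(len(population), size=config.survey_size, replace=False)
    pick.sort()
    sample = population.iloc[pick].reset_index(drop=True)
    ids = pd.Index([f"{k + 1}.1" for k in range(len(sample))], name="id")

    micro = sample[
        [
            "region",
            "age_sex",
            "ethnicity",
            "student",
            "unemployment",
            "gross_weekly_wage",
            "employment_type",
            "household_type",
        ]
    ].copy()
    micro.insert(0, "id", ids)

    model = config.expenditure_model
    factor = {}
    if config.apply_regional_prices:
        rrcpl = select_vintage(config.year)
        lookup = load_coicop_lookup()
        for code in model.categories:
            pc = price_category(code, lookup)
            factor[code] = {
                r: rrcpl.index(r, pc) / 100.0 for r in set(config.region_of_zone)
            }

    records = []
    for code in model.categories:
        amt = sample[f"exp_{code}"].to_numpy().copy()
        if factor:
            amt = amt * sample["region"].map(factor[code]).to_numpy()
        nz = amt > 0
        records.append(
            pd.DataFrame(
                {
                    "id": ids[nz],
                    "coicop": code,
                    "weekly_expenditure_gbp": amt[nz],
                }
            )
        )
    diary = pd.concat(records, ignore_index=True)
    diary = diary.sort_values(["id", "coicop"], kind="stable").reset_index(drop=True)
    return micro, diary


def survey_regional_stats(
    microdata: pd.DataFrame, diary: pd.DataFrame
) -> pd.DataFrame:
    """Survey-side regional means with sampling standard errors.

    Per-person weekly expenditure per category and region over *all*
    surveyed persons (non-purchasers count as zero), the quantity the
    published regional survey averages estimate.  Output columns:
    region, coicop, mean, se, n.
    """
    codes = sorted(diary["coicop"].unique())
    wide = diary.pivot_table(
        index="id", columns="coicop", values="weekly_expenditure_gbp", aggfunc="sum"
    )
    wide = wide.reindex(index=microdata["id"], columns=codes).fillna(0.0)
    wide["region"] = microdata.set_index("id")["region"]
    rows = []
    for region, grp in wide.groupby("region"):
        n = len(grp)
        for code in codes:
            vals = grp[code].to_numpy()
            rows.append(
                {
                    "region": region,
                    "coicop": code,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def deprivation_rank(population: pd.DataFrame) -> pd.DataFrame:
    """Deprivation-like zone ranking derived from the true population.

    Zones are ranked by adult employment rate: rank 1 is the most deprived
    (highest unemployment), the top rank the least deprived — the same
    orientation as the official deprivation rank the external validation
    emulates.  Output columns: zone_code, rank.
    """
    adults = population[population["is_adult"]]
    emp_rate = (
        adults.assign(emp=(adults["unemployment"] == "not_unemployed").astype(float))
        .groupby("zone_code")["emp"]
        .mean()
    )
    rank = emp_rate.rank(method="average").astype(float)
    return pd.DataFrame({"zone_code": rank.index, "rank": rank.to_numpy()})


@dataclass
class SyntheticWorld:
    """A complete generated world plus everything derived from it."""

    config: WorldConfig
    population: pd.DataFrame
    ground_truth: GroundTruth
    constraints: ConstraintBundle
    microdata: pd.DataFrame
    diary: pd.DataFrame
    regional_stats: pd.DataFrame
    deprivation: pd.DataFrame

    @property
    def region_of_zone(self) -> pd.Series:
        return pd.Series(
            self.config.region_of_zone, index=self.config.zone_codes, name="region"
        )


def generate_world(config: WorldConfig | None = None, **kwargs) -> SyntheticWorld:
    """Generate a full synthetic world (population, survey, constraints,
    ground truth).  ``kwargs`` are passed to :func:`default_config` when no
    config is given."""
    if config is None:
        config = default_config(**kwargs)
    population, truth = generate_population(config)
    bundle = tabulate_constraints(population, config)
    micro, diary = sample_survey(population, config)
    stats = survey_regional_stats(micro, diary)
    depriv = deprivation_rank(population)
    return SyntheticWorld(
        config, population, truth, bundle, micro, diary, stats, depriv
    )
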