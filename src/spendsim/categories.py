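"""Categorical taxonomies shared across the pipeline.

The survey microdata and every zone-level constraint table must speak the
same categorical language before reweighting can begin.  This module is the
single source of truth for those category label sets: the 12 UK regions, the
16 age-sex bands (12 adult + 4 child), the four-class ethnicity scheme, the
binary student / unemployment indicators, the three employment types and the
17 household-type labels.  It also loads the commodity code lookup (COICOP,
the UN consumption-purpose hierarchy) that maps each of the 106 leaf codes
to a description, a regional price category and its 80-category collapse.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

REGIONS = [
    "North East",
    "North West",
    "Yorkshire",
    "East Midlands",
    "West Midlands",
    "Eastern",
    "London",
    "South East",
    "South West",
    "Wales",
    "Scotland",
    "Northern Ireland",
]

#: Regions with simulated zones (Northern Ireland individuals may appear in
#: the survey pool but no NI zone is ever a destination).
GB_REGIONS = [r for r in REGIONS if r != "Northern Ireland"]

_AGE_BANDS_ADULT = ["16_24", "25_34", "35_49", "50_64", "65_74", "75_pl"]
_AGE_BANDS_CHILD = ["0_9", "10_15"]

AGE_SEX_ADULT = [f"{s}_{b}" for s in ("F", "M") for b in _AGE_BANDS_ADULT]
AGE_SEX_CHILD = [f"{s}_{b}" for s in ("F", "M") for b in _AGE_BANDS_CHILD]
AGE_SEX_ALL = AGE_SEX_ADULT + AGE_SEX_CHILD

ETHNICITY = ["white", "mixed", "black", "other"]
STUDENT = ["student", "not_student"]
UNEMPLOYMENT = ["unemployed", "not_unemployed"]
EMPLOYMENT_TYPE = ["Employee", "Self-employed", "Other"]

HOUSEHOLD_TYPES = [
    "16_24_dep_n",
    "16_24_dep_y",
    "25_34_dep_n",
    "25_34_dep_y_0_4",
    "25_34_dep_y_5_10",
    "25_34_dep_y_11_pl",
    "35_54_dep_n",
    "35_54_dep_y_0_4",
    "35_54_dep_y_5_10",
    "35_54_dep_y_11_pl",
    "55_64_mph_dep_n",
    "55_64_sph",
    "55_74_dep_y",
    "65_74_mph_dep_n",
    "65_74_sph",
    "75_pl_mph",
    "75_pl_sph",
]

#: Household-type labels an adult in a given age band can plausibly carry.
#: The 50-64 band straddles the 35-54 / 55-64 household groupings, and
#: 55_74_dep_y straddles two bands, so those appear in more than one entry.
HOUSEHOLD_BY_AGE_BAND = {
    "16_24": ["16_24_dep_n", "16_24_dep_y"],
    "25_34": [
        "25_34_dep_n",
        "25_34_dep_y_0_4",
        "25_34_dep_y_5_10",
        "25_34_dep_y_11_pl",
    ],
    "35_49": [
        "35_54_dep_n",
        "35_54_dep_y_0_4",
        "35_54_dep_y_5_10",
        "35_54_dep_y_11_pl",
    ],
    "50_64": [
        "35_54_dep_n",
        "35_54_dep_y_0_4",
        "35_54_dep_y_5_10",
        "35_54_dep_y_11_pl",
        "55_64_mph_dep_n",
        "55_64_sph",
        "55_74_dep_y",
    ],
    "65_74": ["65_74_mph_dep_n", "65_74_sph", "55_74_dep_y"],
    "75_pl": ["75_pl_mph", "75_pl_sph"],
}

#: IPF constraint variables in the default update order.
CONSTRAINT_VARIABLES = [
    "age_sex",
    "household_type",
    "ethnicity",
    "student",
    "unemployment",
    "income",
]

CATEGORY_SETS = {
    "age_sex": AGE_SEX_ADULT,
    "household_type": HOUSEHOLD_TYPES,
    "ethnicity": ETHNICITY,
    "student": STUDENT,
    "unemployment": UNEMPLOYMENT,
}

#: Income constraint categories: eight employee wage deciles, one
#: double-width top bracket, then the two non-employee employment types.
INCOME_CATEGORIES = [
    "p0_p10",
    "p10_p20",
    "p20_p30",
    "p30_p40",
    "p40_p50",
    "p50_p60",
    "p60_p70",
    "p70_p80",
    "p80_p100",
    "self_employed",
    "other",
]

PRICE_CATEGORIES = ["food_nonalcoholic", "alcohol_tobacco", "restaurants_hotels"]


def age_band(age: int) -> str:
    """Return the age-band part of an age-sex label for ``age`` in years.

    Band edges are closed on both sides as printed in the survey
    classification ("25-34" means 25 <= age <= 34); the top band is open.
    """
    if age < 0:
        raise ValueError(f"negative age: {age}")
    for upper, band in [(9, "0_9"), (15, "10_15"), (24, "16_24"), (34, "25_34"),
                        (49, "35_49"), (64, "50_64"), (74, "65_74")]:
        if age <= upper:
            return band
    return "75_pl"


def load_coicop_lookup() -> pd.DataFrame:
    """Load the packaged commodity-code lookup.

    The shipped list is a synthetic stand-in with the same shape as the
    survey's published code list: 106 leaf codes over food and non-alcoholic
    beverages (division 1), alcohol and tobacco (division 2) and catering
    away from home (division 11), each carrying a regional price category
    and the aggregate code it collapses to under the 80-category scheme
    used from 2016 onwards.
    """
    with resources.files("spendsim.data").joinpath(
        "coicop_106_synthetic.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    return df


def collapse_to_80(codes: pd.Series, lookup: pd.DataFrame) -> pd.Series:
    """Map 106-scheme leaf codes to their 80-scheme counterparts."""
    mapping = dict(zip(lookup["code"], lookup["code_80"]))
    unknown = set(codes.unique()) - set(mapping)
    if unknown:
        raise KeyError(f"unknown commodity codes: {sorted(unknown)}")
    return codes.map(mapping)
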