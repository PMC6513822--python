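"""Formatting of survey microdata into the common categorical classes.

Reweighting requires the individual-level survey records and the zone-level
constraint tables to share one categorical vocabulary.  This module maps raw
ages/sexes into the 16 age-sex bands, splits the pool into the adult (16+)
and child (<=15) model populations, validates category labels, and aligns
diary records to calendar years (the survey moved to financial-year releases
in 2015, so building a calendar-year series means dropping and appending
records by their completion date).
"""

from __future__ import annotations

import logging

import pandas as pd

from .categories import (
    AGE_SEX_ADULT,
    AGE_SEX_ALL,
    AGE_SEX_CHILD,
    EMPLOYMENT_TYPE,
    ETHNICITY,
    HOUSEHOLD_TYPES,
    REGIONS,
    STUDENT,
    UNEMPLOYMENT,
    age_band,
)

logger = logging.getLogger(__name__)

MICRODATA_COLUMNS = [
    "id",
    "region",
    "age_sex",
    "ethnicity",
    "student",
    "unemployment",
    "gross_weekly_wage",
    "employment_type",
    "household_type",
]

_LABEL_SETS = {
    "region": set(REGIONS),
    "age_sex": set(AGE_SEX_ALL),
    "ethnicity": set(ETHNICITY),
    "student": set(STUDENT),
    "unemployment": set(UNEMPLOYMENT),
    "employment_type": set(EMPLOYMENT_TYPE),
}


def categorise_age_sex(age: int, sex: str) -> str:
    """Map (age in years, sex) to an age-sex band label.

    Sex is "F" or "M" (case-insensitive, "female"/"male" accepted).  Ages
    15 and under land in the child bands, 16+ in the adult bands; the top
    band is open-ended (75 and 110 share "75_pl").
    """
    s = sex.strip().upper()[:1]
    if s not in ("F", "M"):
        raise ValueError(f"unrecognised sex label: {sex!r}")
    return f"{s}_{age_band(age)}"


def categorise_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Vectorised categorisation of a raw (id, age, sex, ...) table.

    Adds an ``age_sex`` column; unknown ethnicity strings are mapped to the
    "other" catch-all with a logged warning.
    """
    out = raw.copy()
    out["age_sex"] = [
        categorise_age_sex(a, s) for a, s in zip(raw["age"], raw["sex"])
    ]
    if "ethnicity" in out.columns:
        bad = ~out["ethnicity"].isin(ETHNICITY)
        if bad.any():
            logger.warning(
                "%d records with unknown ethnicity mapped to 'other'", bad.sum()
            )
            out.loc[bad, "ethnicity"] = "other"
    return out


def validate_microdata(micro: pd.DataFrame, adult: bool = True) -> None:
    """Check label sets, wage sanity and id uniqueness; raise on violation."""
    missing = set(MICRODATA_COLUMNS) - set(micro.columns)
    if missing and adult:
        raise ValueError(f"microdata missing columns: {sorted(missing)}")
    if micro["id"].duplicated().any():
        dupes = micro.loc[micro["id"].duplicated(), "id"].head()
        raise ValueError(f"duplicate individual ids, e.g. {list(dupes)}")
    for col, allowed in _LABEL_SETS.items():
        if col not in micro.columns:
            continue
        bad = set(micro[col].unique()) - allowed
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    if adult:
        bad_hh = set(micro["household_type"].unique()) - set(HOUSEHOLD_TYPES)
        if bad_hh:
            raise ValueError(f"unknown household_type labels: {sorted(bad_hh)}")
        wages = pd.to_numeric(micro["gross_weekly_wage"])
        if not ((wages >= 0) & wages.notna() & (wages != float("inf"))).all():
            raise ValueError("wages must be finite and nonnegative")


def split_adult_child(micro: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition categorised individuals into the adult (16+) and child
    (15 and under) model pools.  Disjoint and exhaustive by construction."""
    is_child = micro["age_sex"].isin(AGE_SEX_CHILD)
    is_adult = micro["age_sex"].isin(AGE_SEX_ADULT)
    unknown = ~(is_child | is_adult)
    if unknown.any():
        raise ValueError(
            f"unrecognised age_sex labels: "
            f"{sorted(micro.loc[unknown, 'age_sex'].unique())}"
        )
    return micro[is_adult].copy(), micro[is_child].copy()


def filter_calendar_year(
    records: pd.DataFrame, year: int, date_column: str = "survey_date"
) -> pd.DataFrame:
    """Keep only records whose survey completion date falls inside the
    calendar year ``year``.

    Release files straddle years (April-March from 2015 on), so a calendar
    year is assembled by filtering each release on date and concatenating;
    callers pass the concatenation of adjacent releases.  Records with a
    missing date are rejected with a logged count.
    """
    if records.empty:
        return records.copy()
    dates = pd.to_datetime(records[date_column], errors="coerce")
    missing = dates.isna()
    if missing.any():
        logger.warning("%d records dropped for missing survey date", missing.sum())
    keep = (dates.dt.year == year) & ~missing
    return records[keep].copy()
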