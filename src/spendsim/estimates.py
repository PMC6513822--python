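"""Zone-level expenditure estimates from fitted weights and diaries.

A converged weight matrix assigns each survey individual a fractional
presence in every zone.  The zone total for a commodity is the weighted sum
of that commodity's diary amounts, each amount first re-expressed at the
destination zone's regional price level.  Adult and child model outputs are
merged and divided by the combined household population to give the
published unit: pounds per person (all residents) per week.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ipf import WeightMatrix
from .prices import RRCPLTable, price_category


def zone_expenditure(
    weights: WeightMatrix,
    diary: pd.DataFrame,
    microdata_regions: pd.Series,
    region_of_zone: pd.Series,
    rrcpl: RRCPLTable | None = None,
    coicop_lookup: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weighted, price-adjusted zone x commodity expenditure totals.

    total[z, c] = sum_i w[i, z] * amount[i, c] * f(region_i -> region_z, c)

    where f is the regional price factor for c's price category (identity
    when no price table is supplied).  Individuals without a diary entry
    for c contribute zero.  Diary ids must be a subset of the weight
    matrix's individuals.
    """
    stray = set(diary["id"].unique()) - set(weights.individual_ids)
    if stray:
        raise KeyError(f"diary ids missing from weight matrix: {sorted(stray)[:5]}")

    codes = sorted(diary["coicop"].unique())
    amounts = diary.pivot_table(
        index="id", columns="coicop", values="weekly_expenditure_gbp", aggfunc="sum"
    )
    amounts = amounts.reindex(index=weights.individual_ids, columns=codes).fillna(0.0)
    a = amounts.to_numpy()

    if rrcpl is not None:
        if coicop_lookup is None:
            raise ValueError("price adjustment requires the commodity lookup")
        pcats = [price_category(c, coicop_lookup) for c in codes]
        src = microdata_regions.reindex(weights.individual_ids)
        src_idx = np.array(
            [[rrcpl.index(r, pc) for pc in pcats] for r in src]
        )
        a = a / (src_idx / 100.0)  # deflate to UK-average prices
        dest = region_of_zone.reindex(weights.zone_codes)
        dest_idx = np.array(
            [[rrcpl.index(r, pc) for pc in pcats] for r in dest]
        )
        totals = (weights.values.T @ a) * (dest_idx / 100.0)
    else:
        totals = weights.values.T @ a

    return pd.DataFrame(totals, index=weights.zone_codes, columns=codes)


def merge_and_per_capita(
    adult_totals: pd.DataFrame,
    child_totals: pd.DataFrame | None,
    adult_baseline: pd.Series,
    child_baseline: pd.Series,
) -> pd.DataFrame:
    """Merge adult and child model totals into per-person means.

    mean[z, c] = (adult_total + child_total) / (adult_pop + child_pop).
    A missing child diary contributes zero expenditure but the child
    population still enters the denominator (the unit is pounds per
    resident, not per adult).
    """
    zones = adult_totals.index
    if child_totals is None:
        child_totals = pd.DataFrame(
            0.0, index=zones, columns=adult_totals.columns
        )
    if not zones.equals(child_totals.index):
        raise ValueError("adult and child zone sets differ")
    pop = adult_baseline.reindex(zones) + child_baseline.reindex(zones).fillna(0.0)
    if (pop <= 0).any():
        raise ValueError("zero combined population in some zone")
    return adult_totals.add(child_totals, fill_value=0.0).div(pop, axis=0)


def aggregate_categories(
    estimates: pd.DataFrame, members: dict[str, list[str] | str]
) -> pd.DataFrame:
    """Sum member-category estimates into labelled aggregates.

    ``members`` maps an aggregate label to either an explicit code list or
    a code prefix string (dot-hierarchy: prefix "1.1.2" captures every code
    equal to it or starting with "1.1.2.").  Aggregates are exact sums, so
    disjoint aggregates covering all codes add up to the all-products
    total.
    """
    out = {}
    for label, spec in members.items():
        if isinstance(spec, str):
            cols = [
                c
                for c in estimates.columns
                if c == spec or c.startswith(spec + ".")
            ]
            if not cols:
                raise KeyError(f"no codes match prefix {spec!r}")
        else:
            missing = set(spec) - set(estimates.columns)
            if missing:
                raise KeyError(f"unknown member codes: {sorted(missing)}")
            cols = list(spec)
        out[label] = estimates[cols].sum(axis=1)
    return pd.DataFrame(out)


#: Aggregates used in the published maps: divisions 1 and 2 cover food and
#: drink, 2.1 alcoholic drinks, 2.2 tobacco.
STANDARD_AGGREGATES = {
    "all_food_and_drink": "1",
    "alcoholic_drinks": "2.1",
    "tobacco_and_cigarettes": "2.2",
}


def to_long(
    estimates: pd.DataFrame, year: int, lookup: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format output table: year, zone_code, coicop, description,
    mean_weekly_expenditure_gbp."""
    long = estimates.stack().rename("mean_weekly_expenditure_gbp").reset_index()
    long.columns = ["zone_code", "coicop", "mean_weekly_expenditure_gbp"]
    long.insert(0, "year", year)
    if lookup is not None:
        desc = dict(zip(lookup["code"], lookup["description"]))
        long.insert(3, "description", long["coicop"].map(desc).fillna(""))
    return long


def collapse_scheme(
    estimates: pd.DataFrame, lookup: pd.DataFrame
) -> pd.DataFrame:
    """Collapse 106-scheme columns to the 80-category scheme by summing
    each aggregate's members (the away-from-home categories are reported
    only in aggregate from 2016 on)."""
    mapping = dict(zip(lookup["code"], lookup["code_80"]))
    unknown = set(estimates.columns) - set(mapping)
    if unknown:
        raise KeyError(f"codes not in lookup: {sorted(unknown)}")
    grouped = estimates.T.groupby(estimates.columns.map(mapping)).sum().T
    return grouped
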