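"""Relative regional consumer price level (RRCPL) adjustment.

Survey respondents are geocoded only to region, and the reweighting stage
may allocate a respondent to a zone in any region.  Prices differ between
regions (in 2016 food in London cost 2.2% more than the UK average, in
Scotland 0.2% less), so a diary amount recorded at the respondent's home
prices is first deflated to a UK-average price (index 100) and then
reflated to the destination region:

    adjusted = amount * (index_dest / 100) / (index_source / 100)

Detailed per-category indices exist for London, Scotland, Wales and
Northern Ireland; the remaining English regions carry a single aggregate
index repeated across the three price categories.  Two index vintages are
published, 2010 and 2016; years 2008-2012 use the 2010 vintage and
2013-2016 the 2016 vintage.  The packaged 2016 table holds the published
values; the 2010 table is a synthetic stand-in (the published 2010 release
is not redistributable here) with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .categories import PRICE_CATEGORIES

VINTAGE_FILES = {
    2016: "rrcpl_2016.csv",
    2010: "rrcpl_2010_synthetic.csv",
}


@dataclass(frozen=True)
class RRCPLTable:
    """One vintage of regional price indices (UK = 100)."""

    vintage: int
    table: pd.DataFrame  # region x price_category
    detail: dict = field(default_factory=dict)  # region -> "detailed"/"aggregate"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RRCPLTable":
        vintages = df["vintage"].unique()
        if len(vintages) != 1:
            raise ValueError(f"expected a single vintage, got {vintages}")
        wide = df.pivot(index="region", columns="price_category", values="index")
        missing = set(PRICE_CATEGORIES) - set(wide.columns)
        if missing:
            raise ValueError(f"missing price categories: {sorted(missing)}")
        if (wide <= 0).any().any():
            raise ValueError("price indices must be positive")
        detail = df.drop_duplicates("region").set_index("region")["detail_flag"]
        return cls(int(vintages[0]), wide[PRICE_CATEGORIES], dict(detail))

    def index(self, region: str, price_category: str) -> float:
        """Index for ``region`` under ``price_category``.

        Aggregate-only regions store the same value in every category, so
        the column lookup is safe either way.
        """
        if region not in self.table.index:
            raise KeyError(f"region not in RRCPL table: {region!r}")
        if price_category not in self.table.columns:
            raise KeyError(f"unknown price category: {price_category!r}")
        return float(self.table.at[region, price_category])


def load_rrcpl(vintage: int) -> RRCPLTable:
    """Load a packaged RRCPL vintage (2010 or 2016)."""
    try:
        fname = VINTAGE_FILES[vintage]
    except KeyError:
        raise ValueError(f"no RRCPL vintage {vintage}; have {sorted(VINTAGE_FILES)}")
    with resources.files("spendsim.data").joinpath(fname).open(
        "r", encoding="utf-8"
    ) as fh:
        return RRCPLTable.from_frame(pd.read_csv(fh))


def select_vintage(year: int) -> RRCPLTable:
    """Pick the index vintage closest to ``year``: 2008-2012 -> 2010,
    2013-2016 -> 2016."""
    if not 2008 <= year <= 2016:
        raise ValueError(f"year {year} outside supported range 2008-2016")
    return load_rrcpl(2010 if year <= 2012 else 2016)


def price_category(coicop: str, lookup: pd.DataFrame) -> str:
    """Price category for a commodity code, from the code lookup table.

    The lookup file is authoritative; every code in the 106-category list
    maps to exactly one of food_nonalcoholic / alcohol_tobacco /
    restaurants_hotels.
    """
    match = lookup.loc[lookup["code"] == coicop, "price_category"]
    if match.empty:
        raise KeyError(f"commodity code not in lookup: {coicop!r}")
    return str(match.iloc[0])


def adjust_expenditure(
    amount: float,
    source_region: str,
    dest_region: str,
    category: str,
    table: RRCPLTable,
) -> float:
    """Re-express ``amount`` recorded at ``source_region`` prices in
    ``dest_region`` prices via the UK-average level."""
    if amount < 0:
        raise ValueError("expenditure must be nonnegative")
    return amount * table.index(dest_region, category) / table.index(
        source_region, category
    )


def adjustment_factors(
    regions: pd.Index, table: RRCPLTable
) -> pd.DataFrame:
    """Region x price-category matrix of index/100 factors, for vectorised
    adjustment of whole diaries."""
    out = table.table.loc[list(regions)] / 100.0
    out.index = regions
    return out
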