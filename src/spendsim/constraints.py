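"""Zone-level constraint tables: construction, scaling, harmonisation.

The reweighting stage needs, for every zone, one table per constraint
variable whose categories partition the 16+ household population and whose
total equals that zone's baseline.  The baseline itself is the mid-year
population estimate minus communal-establishment residents (care homes,
student halls...), leaving household residents only — the population the
expenditure survey samples.  Every other constraint is then rescaled,
zone by zone, so its category proportions are preserved but its total
matches the baseline.

Income arrives as eight published wage percentiles (P10..P80) per zone
plus employee / self-employed / other headcounts; it becomes an
eleven-category constraint — eight employee deciles, a double-width
P80-P100 bracket, and the two non-employee types — before scaling.
Fractional counts are kept throughout: the targets are real-valued and no
integerisation is performed.

A minority of zones lack some constraints (small samples make publication
disclosive), so the effective constraint set is adjusted per zone: binary
variables are dropped outright, while partially complete ethnicity tables
are re-categorised by folding the missing category into the catch-all and
relabelling the microdata identically for that zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import INCOME_CATEGORIES

logger = logging.getLogger(__name__)

PERCENTILE_COLUMNS = ["p10", "p20", "p30", "p40", "p50", "p60", "p70", "p80"]

#: Pre-scaling decile weights: eight single deciles and one double-width
#: top bracket (employees/10 each, employees/5 for P80-P100).
_DECILE_WEIGHTS = np.array([1, 1, 1, 1, 1, 1, 1, 1, 2], dtype=float)


@dataclass
class ConstraintTable:
    """Per-zone counts per category for one constraint variable.

    ``counts`` is a zone x category frame; NaN marks a category unavailable
    for that zone (resolved by :func:`harmonise_missing` before fitting).
    """

    variable: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError(f"negative counts in {self.variable} constraint")

    @property
    def zones(self) -> pd.Index:
        return self.counts.index

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1, skipna=True)


def build_baseline(
    midyear: pd.DataFrame, communal: pd.DataFrame
) -> tuple[pd.Series, ConstraintTable]:
    """Household-resident baseline: mid-year counts minus communal residents.

    Both inputs are zone x age-sex frames.  Communal counts are observed
    once (census year) and assumed constant across study years, so the same
    ``communal`` frame is reused for every year.  Negative cells signal
    inconsistent inputs and are clamped to zero with a logged warning.
    """
    communal = communal.reindex(index=midyear.index, columns=midyear.columns).fillna(
        0.0
    )
    cells = midyear - communal
    neg = cells < 0
    if neg.to_numpy().any():
        logger.warning(
            "%d negative baseline cells clamped to zero (communal > midyear)",
            int(neg.to_numpy().sum()),
        )
        cells = cells.clip(lower=0.0)
    table = ConstraintTable("age_sex", cells)
    return cells.sum(axis=1), table


def scale_constraint(raw: ConstraintTable, baseline: pd.Series) -> ConstraintTable:
    """Rescale each zone's row to sum to that zone's baseline.

    Category proportions are preserved exactly; NaN cells (unavailable
    categories) are left NaN and excluded from the row total.  A zone whose
    available cells sum to zero cannot be scaled and is marked wholly
    unavailable (all-NaN row).
    """
    counts = raw.counts.reindex(baseline.index)
    totals = counts.sum(axis=1, skipna=True)
    dead = totals <= 0
    if dead.any():
        logger.warning(
            "constraint %s unavailable for %d zone(s) with zero row total",
            raw.variable,
            int(dead.sum()),
        )
    factors = baseline.where(~dead) / totals.where(~dead)
    return ConstraintTable(raw.variable, counts.mul(factors, axis=0))


@dataclass
class IncomeConstraint:
    """Income constraint plus the zone-specific bracket boundaries.

    ``prescale`` holds the bracket counts before baseline scaling (eight
    equal deciles, a double top bracket, self-employed and other), which is
    the form the published worked examples print.
    """

    boundaries: pd.DataFrame  # zone x p10..p80 (pounds)
    prescale: ConstraintTable
    scaled: ConstraintTable


def build_income_constraint(
    earnings: pd.DataFrame, baseline: pd.Series
) -> IncomeConstraint:
    """Build the eleven-category income constraint from published wage
    percentiles and employment-type headcounts.

    ``earnings`` columns: ``zone_code`` (or index), ``p10``..``p80``,
    ``employees``, ``self_employed``, ``other``.  Employee counts are
    spread over the brackets in the fixed 1:...:1:2 decile pattern.  A
    missing percentile boundary merges the two brackets it would separate;
    the merged bracket keeps the label of its lowest constituent decile
    (the same label zone-specific wage categorisation produces when it
    skips the missing boundary) and carries the summed decile mass.  Zones
    with non-monotone or wholly absent boundaries are marked unavailable
    (all-NaN row).
    """
    df = earnings.set_index("zone_code") if "zone_code" in earnings.columns else earnings
    df = df.reindex(baseline.index)
    bounds = df[PERCENTILE_COLUMNS].astype(float)

    vals = bounds.to_numpy()
    present = ~np.isnan(vals)
    bad = ~present.any(axis=1)
    for i in range(len(df)):
        row = vals[i][present[i]]
        if row.size and not (np.diff(row) > 0).all():
            bad[i] = True
    if bad.any():
        logger.warning(
            "income constraint unavailable for %d zone(s) with non-monotone "
            "or absent wage boundaries",
            int(bad.sum()),
        )

    employees = df["employees"].astype(float).to_numpy()
    decile = np.zeros((len(df), 9))
    merged_zones = 0
    for i in range(len(df)):
        if bad[i]:
            continue
        # bracket j spans [b[j-1], b[j]); a missing b[j-1] folds bracket j
        # into the bracket below it
        label = 0
        for j in range(9):
            if j > 0 and not np.isnan(vals[i, j - 1]):
                label = j
            decile[i, label] += _DECILE_WEIGHTS[j] * employees[i] / 10.0
        if not present[i].all():
            merged_zones += 1
    if merged_zones:
        logger.info(
            "income brackets merged at missing boundaries for %d zone(s)",
            merged_zones,
        )

    counts = pd.DataFrame(decile, index=df.index, columns=INCOME_CATEGORIES[:9])
    counts["self_employed"] = df["self_employed"].astype(float)
    counts["other"] = df["other"].astype(float)
    counts.loc[bad] = np.nan
    bounds.loc[bad] = np.nan

    prescale = ConstraintTable("income", counts)
    scaled = scale_constraint(prescale, baseline)
    return IncomeConstraint(bounds, prescale, scaled)


def assign_income_categories(
    wages: np.ndarray, employment_type: np.ndarray, boundary_row: np.ndarray
) -> np.ndarray:
    """Zone-specific income category codes for the microdata.

    Employees are bracketed by the zone's own wage boundaries (a wage below
    P10 -> bracket 0, at or above P80 -> bracket 8); the self-employed and
    other types land in categories 9 and 10 regardless of wage.  NaN
    boundaries are skipped: the adjoining brackets have been merged by
    harmonisation, and searchsorted over the remaining finite boundaries
    assigns wages to the merged bracket's lowest constituent decile, which
    is exactly where the merged target mass lives.
    """
    finite = ~np.isnan(boundary_row)
    edges = boundary_row[finite]
    decile_of_edge = np.flatnonzero(finite)  # bracket index above each edge
    pos = np.searchsorted(edges, wages, side="right")
    codes = np.zeros(len(wages), dtype=np.int64)
    nonzero = pos > 0
    codes[nonzero] = decile_of_edge[pos[nonzero] - 1] + 1
    codes[employment_type == "Self-employed"] = 9
    codes[employment_type == "Other"] = 10
    return codes


@dataclass
class HarmonisedConstraints:
    """Effective, NaN-free constraint system after missing-data handling.

    ``category_maps[var][zone]`` relabels microdata categories for zones
    where a missing category was folded into the catch-all; IPF applies the
    same relabelling to the survey side so both sides stay consistent.
    """

    constraints: dict[str, ConstraintTable]
    available: pd.DataFrame  # zone x variable bool
    category_maps: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)
    income_boundaries: pd.DataFrame | None = None

    def variables_for_zone(self, zone: str) -> list[str]:
        return [v for v in self.constraints if bool(self.available.at[zone, v])]


_BINARY_VARIABLES = ("student", "unemployment")
_MANDATORY = ("age_sex", "household_type")


def harmonise_missing(
    constraints: dict[str, ConstraintTable],
    manifest: pd.DataFrame | None = None,
    income_boundaries: pd.DataFrame | None = None,
    catch_all: str = "other",
) -> HarmonisedConstraints:
    """Resolve per-zone constraint availability into an effective system.

    Age-sex and household type must be complete for every zone (the model
    runs on these as a minimum); their absence is fatal.  Binary variables
    are available per zone or not at all.  A partially complete ethnicity
    row keeps its present categories and folds each missing one into
    ``catch_all``, recording the relabelling so the microdata can follow.
    Income bracket merges at missing percentile boundaries are resolved
    upstream in :func:`build_income_constraint`; an income row that is
    still incomplete here is treated as wholly unavailable.
    """
    zones = constraints["age_sex"].zones if "age_sex" in constraints else None
    if zones is None:
        raise ValueError("age_sex constraint is mandatory")

    available = pd.DataFrame(True, index=zones, columns=list(constraints))
    if manifest is not None:
        available &= manifest.reindex(index=zones, columns=list(constraints)).fillna(
            False
        )
    out: dict[str, ConstraintTable] = {}
    category_maps: dict[str, dict[str, dict[str, str]]] = {}

    for var, ct in constraints.items():
        counts = ct.counts.reindex(zones)
        row_dead = counts.isna().all(axis=1) | (counts.sum(axis=1, skipna=True) <= 0)
        available[var] &= ~row_dead
        if var in _MANDATORY:
            if not available[var].all():
                missing = list(available.index[~available[var]])
                raise ValueError(f"{var} constraint missing for zones {missing}")
            if counts.isna().any().any():
                raise ValueError(f"{var} constraint has missing categories")
            out[var] = ConstraintTable(var, counts)
            continue
        if var in _BINARY_VARIABLES:
            partial = counts.isna().any(axis=1) & ~row_dead
            if partial.any():
                logger.warning(
                    "%s partially missing for %d zone(s); dropped there",
                    var,
                    int(partial.sum()),
                )
                available[var] &= ~partial
            out[var] = ConstraintTable(var, counts.where(available[var], np.nan))
            continue
        if var == "income":
            # bracket merging already resolved in build_income_constraint;
            # any remaining NaN means the zone has no usable income data
            partial = counts.isna().any(axis=1) & ~row_dead
            available[var] &= ~partial
            out[var] = ConstraintTable(var, counts.where(available[var], np.nan))
            continue
        # categorical with catch-all (ethnicity)
        merged, zone_maps = _merge_catch_all(counts, available[var], catch_all, var)
        out[var] = ConstraintTable(var, merged)
        if zone_maps:
            category_maps[var] = zone_maps

    bounds = None
    if income_boundaries is not None:
        bounds = income_boundaries.reindex(zones)
    return HarmonisedConstraints(out, available, category_maps, bounds)


def _merge_catch_all(
    counts: pd.DataFrame, avail: pd.Series, catch_all: str, var: str
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    if catch_all not in counts.columns:
        raise ValueError(f"{var} constraint lacks catch-all category {catch_all!r}")
    merged = counts.copy()
    zone_maps: dict[str, dict[str, str]] = {}
    partial = counts.isna().any(axis=1) & avail
    for zone in counts.index[partial]:
        row = counts.loc[zone]
        if pd.isna(row[catch_all]):
            # catch-all itself absent: cannot merge into it, drop the zone
            avail.at[zone] = False
            merged.loc[zone] = np.nan
            logger.warning("%s dropped for zone %s: catch-all missing", var, zone)
            continue
        gone = [c for c in counts.columns if pd.isna(row[c])]
        zone_maps[zone] = {c: catch_all for c in gone}
        logger.info("%s for zone %s re-categorised: %s -> %s", var, zone, gone,
                    catch_all)
    merged = merged.where(avail, np.nan)
    return merged, zone_maps


def audit_availability(manifests: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Zone-availability audit: years as rows, constraint variables as
    columns, each cell the number of zones with that constraint available
    that year."""
    rows = {year: m.sum(axis=0).astype(int) for year, m in manifests.items()}
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "year"
    return out
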