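"""Model / results interface tying the pipeline stages together.

:class:`ExpenditureMicrosimulation` is built from the survey microdata, the
expenditure diary and the zone-level inputs; :meth:`fit` runs baseline
construction, constraint scaling, missing-data harmonisation and the adult
and child IPF models, returning a :class:`MicrosimulationResults` that
carries the weight matrices and diagnostics and exposes the estimation and
validation steps as methods.

Typical use::

    world = synthetic_data.generate_world(seed=1)
    model = ExpenditureMicrosimulation.from_world(world)
    res = model.fit(tol=1e-4, max_iter=50)
    print(res.summary())
    est = res.expenditure()          # zone x commodity, pounds/person/week
    r = res.internal_validation()    # per-zone correlation
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimates as est_mod
from . import validation as val_mod
from .categories import (
    AGE_SEX_ADULT,
    AGE_SEX_CHILD,
    CONSTRAINT_VARIABLES,
    INCOME_CATEGORIES,
    load_coicop_lookup,
)
from .constraints import (
    ConstraintTable,
    HarmonisedConstraints,
    assign_income_categories,
    build_baseline,
    build_income_constraint,
    harmonise_missing,
    scale_constraint,
)
from .ipf import (
    ConstraintSpec,
    FitDiagnostics,
    WeightMatrix,
    fit_child_model,
    ipf_fit,
)
from .microdata_prep import split_adult_child, validate_microdata
from .prices import RRCPLTable, select_vintage

logger = logging.getLogger(__name__)


class ExpenditureMicrosimulation:
    """Small-area expenditure model: survey microdata reweighted to zones.

    Parameters
    ----------
    microdata : categorised survey individuals (adults and children).
    diary : long table (id, coicop, weekly_expenditure_gbp).
    raw_constraints : variable -> ConstraintTable of raw per-zone counts
        for household_type, ethnicity, student, unemployment (age_sex comes
        from the mid-year/communal inputs; income from ``earnings``).
    midyear_adult, communal_adult : zone x adult age-sex count frames.
    midyear_child, communal_child : zone x child age-sex count frames.
    earnings : published wage percentiles + employment headcounts per zone.
    region_of_zone : zone -> region label.
    year : estimation year; selects the price index vintage.
    manifest : optional zone x variable availability booleans.
    child_diary : optional child expenditure diary (defaults to none:
        children carry zero expenditure but still count as residents).
    """

    def __init__(
        self,
        microdata: pd.DataFrame,
        diary: pd.DataFrame,
        raw_constraints: dict[str, ConstraintTable],
        midyear_adult: pd.DataFrame,
        communal_adult: pd.DataFrame,
        midyear_child: pd.DataFrame,
        communal_child: pd.DataFrame,
        earnings: pd.DataFrame,
        region_of_zone: pd.Series,
        *,
        year: int = 2013,
        manifest: pd.DataFrame | None = None,
        child_diary: pd.DataFrame | None = None,
        rrcpl: RRCPLTable | None = None,
        coicop_lookup: pd.DataFrame | None = None,
    ) -> None:
        self.adults, self.children = split_adult_child(microdata)
        validate_microdata(self.adults, adult=True)
        self.diary = diary
        self.child_diary = child_diary
        self.raw_constraints = raw_constraints
        self.midyear_adult = midyear_adult
        self.communal_adult = communal_adult
        self.midyear_child = midyear_child
        self.communal_child = communal_child
        self.earnings = earnings
        self.region_of_zone = region_of_zone
        self.year = year
        self.manifest = manifest
        self.rrcpl = rrcpl if rrcpl is not None else select_vintage(year)
        self.coicop_lookup = (
            coicop_lookup if coicop_lookup is not None else load_coicop_lookup()
        )

    @classmethod
    def from_world(cls, world, **kwargs) -> "ExpenditureMicrosimulation":
        """Build directly from a :class:`~spendsim.synthetic_data.SyntheticWorld`."""
        b = world.constraints
        raw = {k: v for k, v in b.raw.items() if k != "age_sex"}
        return cls(
            world.microdata,
            world.diary,
            raw,
            b.midyear_adult,
            b.communal_adult,
            b.midyear_child,
            b.communal_child,
            b.earnings,
            world.region_of_zone,
            year=world.config.year,
            **kwargs,
        )

    # ------------------------------------------------------------------

    def _prepare(self) -> tuple[pd.Series, pd.Series, HarmonisedConstraints, ConstraintTable]:
        baseline_adult, age_sex_ct = build_baseline(
            self.midyear_adult, self.communal_adult
        )
        baseline_child, child_ct = build_baseline(
            self.midyear_child, self.communal_child
        )
        income = build_income_constraint(self.earnings, baseline_adult)
        scaled: dict[str, ConstraintTable] = {"age_sex": age_sex_ct}
        for var in ("household_type", "ethnicity", "student", "unemployment"):
            if var in self.raw_constraints:
                scaled[var] = scale_constraint(
                    self.raw_constraints[var], baseline_adult
                )
        scaled["income"] = income.scaled
        harmonised = harmonise_missing(
            scaled, self.manifest, income_boundaries=income.boundaries
        )
        child_ct = ConstraintTable(
            "age_sex_child", child_ct.counts.reindex(columns=AGE_SEX_CHILD)
        )
        self._baseline_adult = baseline_adult
        self._baseline_child = baseline_child
        return baseline_adult, baseline_child, harmonised, child_ct

    def _build_specs(
        self, harmonised: HarmonisedConstraints
    ) -> list[ConstraintSpec]:
        adults = self.adults
        n = len(adults)
        zones = harmonised.constraints["age_sex"].zones
        n_zones = len(zones)
        specs: list[ConstraintSpec] = []
        for var in CONSTRAINT_VARIABLES:
            if var not in harmonised.constraints:
                continue
            ct = harmonised.constraints[var]
            if var == "income":
                bounds = harmonised.income_boundaries.to_numpy()
                wages = adults["gross_weekly_wage"].to_numpy(dtype=float)
                etype = adults["employment_type"].to_numpy()
                codes = np.empty((n, n_zones), dtype=np.int64)
                for z in range(n_zones):
                    row = bounds[z]
                    if np.isnan(row).all():
                        codes[:, z] = 0  # unavailable zone; update skipped
                    else:
                        codes[:, z] = assign_income_categories(wages, etype, row)
                specs.append(
                    ConstraintSpec(
                        "income",
                        codes,
                        len(INCOME_CATEGORIES),
                        ct.counts.to_numpy(),
                        INCOME_CATEGORIES,
                    )
                )
                continue
            cats = ct.categories
            cat_index = {c: k for k, c in enumerate(cats)}
            base_codes = adults[var].map(cat_index)
            if base_codes.isna().any():
                bad = sorted(adults.loc[base_codes.isna(), var].unique())
                raise ValueError(f"microdata {var} labels not in constraint: {bad}")
            base_codes = base_codes.to_numpy(dtype=np.int64)
            zone_maps = harmonised.category_maps.get(var)
            if zone_maps:
                codes = np.tile(base_codes[:, None], (1, n_zones))
                zpos = {z: i for i, z in enumerate(zones)}
                for zone, mapping in zone_maps.items():
                    zi = zpos[zone]
                    for orig, tgt in mapping.items():
                        codes[adults[var].to_numpy() == orig, zi] = cat_index[tgt]
                spec_codes = codes
            else:
                spec_codes = base_codes
            specs.append(
                ConstraintSpec(
                    var, spec_codes, len(cats), ct.counts.to_numpy(), list(cats)
                )
            )
        return specs

    def fit(
        self,
        *,
        tol: float = 1e-4,
        max_iter: int = 50,
        order: list[str] | None = None,
        empty_cell: str = "drop",
    ) -> "MicrosimulationResults":
        """Run the adult and child models to convergence.

        The adult model cycles the constraint variables in ``order``
        (default: age_sex, household_type, ethnicity, student,
        unemployment, income) until the largest per-zone relative TAE
        drops below ``tol`` or ``max_iter`` sweeps elapse.  The child
        model is a one-sweep closed form.
        """
        baseline_adult, baseline_child, harmonised, child_ct = self._prepare()
        specs = self._build_specs(harmonised)
        weights, diag = ipf_fit(
            specs,
            baseline_adult,
            pd.Index(self.adults["id"]),
            max_iter=max_iter,
            tol=tol,
            order=order,
            empty_cell=empty_cell,
        )
        child_weights = None
        if len(self.children):
            cat_index = {c: k for k, c in enumerate(AGE_SEX_CHILD)}
            codes = self.children["age_sex"].map(cat_index).to_numpy(dtype=np.int64)
            child_weights = fit_child_model(
                codes, child_ct.counts, pd.Index(self.children["id"])
            )
        return MicrosimulationResults(
            model=self,
            weights=weights,
            child_weights=child_weights,
            diagnostics=diag,
            specs=specs,
            harmonised=harmonised,
            baseline_adult=baseline_adult,
            baseline_child=baseline_child,
        )


@dataclass
class MicrosimulationResults:
    """Fitted weights plus everything derived from them."""

    model: ExpenditureMicrosimulation
    weights: WeightMatrix
    child_weights: WeightMatrix | None
    diagnostics: FitDiagnostics
    specs: list[ConstraintSpec]
    harmonised: HarmonisedConstraints
    baseline_adult: pd.Series
    baseline_child: pd.Series
    _internal_cache: tuple[pd.Series, pd.DataFrame] | None = field(
        default=None, repr=False
    )

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    def internal_validation(self) -> pd.Series:
        """Per-zone correlation between constraint targets and simulated
        marginals (concatenated over available constraints)."""
        if self._internal_cache is None:
            self._internal_cache = val_mod.internal_validation(
                self.weights, self.specs
            )
        return self._internal_cache[0]

    def internal_validation_by_constraint(self) -> pd.DataFrame:
        self.internal_validation()
        return self._internal_cache[1]

    def expenditure(self, scheme: int = 106) -> pd.DataFrame:
        """Zone x commodity mean weekly expenditure, pounds per person.

        Adult totals are price-adjusted from each individual's source
        region to the destination zone's region; the child model
        contributes population (and any child diary) before the per-capita
        division.  ``scheme=80`` collapses away-from-home categories to
        their aggregates.
        """
        m = self.model
        adult_regions = m.adults.set_index("id")["region"]
        totals = est_mod.zone_expenditure(
            self.weights,
            m.diary,
            adult_regions,
            m.region_of_zone,
            m.rrcpl,
            m.coicop_lookup,
        )
        child_totals = None
        if m.child_diary is not None and self.child_weights is not None:
            child_regions = m.children.set_index("id")["region"]
            child_totals = est_mod.zone_expenditure(
                self.child_weights,
                m.child_diary,
                child_regions,
                m.region_of_zone,
                m.rrcpl,
                m.coicop_lookup,
            ).reindex(columns=totals.columns, fill_value=0.0)
        out = est_mod.merge_and_per_capita(
            totals, child_totals, self.baseline_adult, self.baseline_child
        )
        if scheme == 80:
            out = est_mod.collapse_scheme(out, m.coicop_lookup)
        elif scheme != 106:
            raise ValueError("scheme must be 106 or 80")
        return out

    def aggregates(
        self, members: dict[str, list[str] | str] | None = None
    ) -> pd.DataFrame:
        """Zone-level aggregate estimates (default: all food and drink,
        alcoholic drinks, tobacco and cigarettes)."""
        members = members or {
            k: v
            for k, v in est_mod.STANDARD_AGGREGATES.items()
        }
        est = self.expenditure()
        usable = {
            label: spec
            for label, spec in members.items()
            if not isinstance(spec, str)
            or any(c == spec or c.startswith(spec + ".") for c in est.columns)
        }
        return est_mod.aggregate_categories(est, usable)

    def regional_comparison(self, survey_stats: pd.DataFrame) -> pd.DataFrame:
        """External validation (a): aggregate zone estimates to regions and
        flag agreement with survey means within 1.96 SE."""
        pops = self.baseline_adult + self.baseline_child.reindex(
            self.baseline_adult.index
        ).fillna(0.0)
        return val_mod.regional_comparison(
            self.expenditure(), pops, self.model.region_of_zone, survey_stats
        )

    def rank_correlation(
        self, external_rank: pd.Series, aggregates: dict[str, pd.Series] | None = None
    ) -> pd.DataFrame:
        """External validation (b): Spearman rank correlation of commodity
        aggregates against an external zone ranking."""
        if aggregates is None:
            agg = self.aggregates()
            aggregates = {c: agg[c] for c in agg.columns}
        return val_mod.rank_tests_table(external_rank, aggregates)

    def validation_report(
        self,
        survey_stats: pd.DataFrame | None = None,
        external_rank: pd.Series | None = None,
    ) -> val_mod.ValidationReport:
        internal, by_c = val_mod.internal_validation(self.weights, self.specs)
        report = val_mod.ValidationReport(internal, by_c)
        if survey_stats is not None:
            report.regional = self.regional_comparison(survey_stats)
        if external_rank is not None:
            report.rank_tests = self.rank_correlation(external_rank)
        return report

    def summary(self) -> str:
        """Human-readable fit summary."""
        d = self.diagnostics
        r = self.internal_validation().dropna()
        n_zones = len(self.weights.zone_codes)
        lines = [
            "Expenditure microsimulation results",
            "===================================",
            f"adult individuals:      {self.weights.values.shape[0]}",
            f"child individuals:      "
            f"{0 if self.child_weights is None else self.child_weights.values.shape[0]}",
            f"zones:                  {n_zones}",
            f"constraints fitted:     {', '.join(s.name for s in self.specs)}",
            f"sweeps:                 {d.iterations}",
            f"converged:              {d.converged}",
            f"max zone rel. TAE:      {d.final_zone_relative_error.max():.3e}",
            f"empty cells dropped:    {len(d.dropped_cells)}",
            f"internal r (min/med):   {r.min():.6f} / {r.median():.6f}",
            f"total population:       "
            f"{(self.baseline_adult.sum() + self.baseline_child.sum()):,.0f}",
        ]
        return "\n".join(lines)
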