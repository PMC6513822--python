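"""Constraint construction and scaling, including the published worked
examples (three local-authority districts with printed baselines, raw
category counts, wage percentiles and bracket counts)."""

from importlib import resources

import numpy as np
import pandas as pd
import pytest

from spendsim.categories import INCOME_CATEGORIES
from spendsim.constraints import (
    PERCENTILE_COLUMNS,
    ConstraintTable,
    assign_income_categories,
    audit_availability,
    build_baseline,
    build_income_constraint,
    harmonise_missing,
    scale_constraint,
)


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("spendsim.data").joinpath(f"worked_examples/{name}").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


@pytest.fixture(scope="module")
def printed_baseline() -> pd.Series:
    df = _fixture("baseline_2008.csv").set_index("zone_code")
    return df["baseline_16plus"].astype(float)


@pytest.fixture(scope="module")
def printed_constraints() -> dict[str, pd.DataFrame]:
    long = _fixture("constraints_2008.csv")
    return {
        var: grp.pivot(index="zone_code", columns="category", values="count").astype(
            float
        )
        for var, grp in long.groupby("variable")
    }


@pytest.fixture(scope="module")
def printed_earnings() -> pd.DataFrame:
    return _fixture("earnings_2008.csv")


class TestBuildBaseline:
    def _frames(self):
        midyear = pd.DataFrame(
            {"F_16_24": [100.0, 50.0], "M_75_pl": [40.0, 30.0]},
            index=pd.Index(["A", "B"], name="zone_code"),
        )
        return midyear

    def test_zero_communal_is_identity(self):
        midyear = self._frames()
        base, ct = build_baseline(midyear, midyear * 0.0)
        pd.testing.assert_frame_equal(ct.counts, midyear)
        pd.testing.assert_series_equal(base, midyear.sum(axis=1))

    def test_full_communal_cell_goes_to_zero(self):
        midyear = self._frames()
        communal = midyear * 0.0
        communal.loc["A", "F_16_24"] = 100.0
        base, ct = build_baseline(midyear, communal)
        assert ct.counts.loc["A", "F_16_24"] == 0.0

    def test_negative_cells_clamped_with_warning(self, caplog):
        midyear = self._frames()
        communal = midyear * 0.0
        communal.loc["A", "F_16_24"] = 150.0
        with caplog.at_level("WARNING"):
            base, ct = build_baseline(midyear, communal)
        assert ct.counts.loc["A", "F_16_24"] == 0.0
        assert "clamped" in caplog.text

    def test_zone_totals_equal_cell_sums(self, tiny_world):
        b = tiny_world.constraints
        base, ct = build_baseline(b.midyear_adult, b.communal_adult)
        # summation oracle: explicit per-zone python sum
        for zone in ct.counts.index:
            assert base[zone] == pytest.approx(
                sum(ct.counts.loc[zone].tolist()), rel=1e-12
            )


class TestScaleConstraint:
    def test_printed_ethnicity_sums_scale_to_printed_baselines(
        self, printed_constraints, printed_baseline
    ):
        raw = ConstraintTable("ethnicity", printed_constraints["ethnicity"])
        scaled = scale_constraint(raw, printed_baseline)
        sums = scaled.counts.sum(axis=1)
        assert sums["E08000002"] == pytest.approx(144258, abs=1e-6)
        assert sums["E08000003"] == pytest.approx(364549, abs=1e-6)
        assert sums["E08000004"] == pytest.approx(170259, abs=1e-6)

    def test_printed_counts_already_at_baseline_are_unchanged(
        self, printed_constraints, printed_baseline
    ):
        # the published extract sums exactly to the baseline, so scaling
        # must be the identity (idempotence)
        raw = ConstraintTable("student", printed_constraints["student"])
        scaled = scale_constraint(raw, printed_baseline)
        pd.testing.assert_frame_equal(
            scaled.counts, printed_constraints["student"], check_like=True
        )

    def test_scale_invariance_to_positive_rescaling(
        self, printed_constraints, printed_baseline
    ):
        raw = printed_constraints["ethnicity"]
        s1 = scale_constraint(ConstraintTable("ethnicity", raw), printed_baseline)
        s2 = scale_constraint(
            ConstraintTable("ethnicity", raw * 2.0), printed_baseline
        )
        pd.testing.assert_frame_equal(s1.counts, s2.counts)

    def test_zero_rowsum_marks_zone_unavailable(self, printed_baseline, caplog):
        raw = pd.DataFrame(
            {"student": [0.0, 10.0, 5.0], "not_student": [0.0, 20.0, 5.0]},
            index=printed_baseline.index,
        )
        with caplog.at_level("WARNING"):
            scaled = scale_constraint(ConstraintTable("student", raw), printed_baseline)
        assert scaled.counts.iloc[0].isna().all()
        assert scaled.counts.iloc[1:].notna().all().all()


class TestIncomeConstraint:
    def test_printed_decile_counts_reproduced_exactly(
        self, printed_earnings, printed_baseline
    ):
        inc = build_income_constraint(printed_earnings, printed_baseline)
        pre = inc.prescale.counts
        assert pre.loc["E08000002", "p0_p10"] == pytest.approx(7529.6)
        assert pre.loc["E08000002", "p80_p100"] == pytest.approx(15059.2)
        assert pre.loc["E08000003", "p0_p10"] == pytest.approx(16874.4)
        assert pre.loc["E08000003", "p80_p100"] == pytest.approx(33748.8)
        assert pre.loc["E08000004", "p0_p10"] == pytest.approx(8196.9)
        assert pre.loc["E08000004", "p80_p100"] == pytest.approx(16393.8)

    def test_eight_equal_brackets_and_one_double(self, printed_earnings,
                                                 printed_baseline):
        inc = build_income_constraint(printed_earnings, printed_baseline)
        deciles = inc.prescale.counts[INCOME_CATEGORIES[:8]]
        top = inc.prescale.counts["p80_p100"]
        for zone in deciles.index:
            row = deciles.loc[zone].to_numpy()
            assert np.allclose(row, row[0])
            assert top[zone] == pytest.approx(2 * row[0])

    def test_scaled_income_rows_sum_to_baseline(self, printed_earnings,
                                                printed_baseline):
        inc = build_income_constraint(printed_earnings, printed_baseline)
        sums = inc.scaled.counts.sum(axis=1)
        for zone, b in printed_baseline.items():
            assert sums[zone] == pytest.approx(b, rel=1e-9)

    def test_zero_employees_leaves_mass_with_other_types(self, printed_baseline):
        earnings = pd.DataFrame(
            {
                "zone_code": printed_baseline.index,
                **{c: [np.nan, 100.0, 100.0] for c in PERCENTILE_COLUMNS},
                "employees": [0, 10, 10],
                "self_employed": [5, 1, 1],
                "other": [5, 1, 1],
            }
        )
        # give monotone boundaries to the rows that have employees
        for k, c in enumerate(PERCENTILE_COLUMNS):
            earnings.loc[1:, c] = 100.0 + 10 * k
        earnings.loc[0, PERCENTILE_COLUMNS] = np.linspace(50, 120, 8)
        inc = build_income_constraint(earnings, printed_baseline)
        row = inc.prescale.counts.iloc[0]
        assert (row[INCOME_CATEGORIES[:9]] == 0).all()
        assert row["self_employed"] == 5 and row["other"] == 5

    def test_non_monotone_boundaries_mark_zone_unavailable(
        self, printed_earnings, printed_baseline, caplog
    ):
        bad = printed_earnings.copy()
        bad.loc[0, "p30"] = 1.0  # below p20: non-monotone
        with caplog.at_level("WARNING"):
            inc = build_income_constraint(bad, printed_baseline)
        assert inc.prescale.counts.iloc[0].isna().all()
        assert inc.boundaries.iloc[0].isna().all()

    def test_missing_boundary_merges_adjacent_brackets(
        self, printed_earnings, printed_baseline
    ):
        part = printed_earnings.copy()
        part.loc[0, "p30"] = np.nan  # E08000002 loses the P30 boundary
        inc = build_income_constraint(part, printed_baseline)
        row = inc.prescale.counts.loc["E08000002"]
        # brackets P20-P30 and P30-P40 merge under the lower label
        assert row["p20_p30"] == pytest.approx(2 * 7529.6)
        assert row["p30_p40"] == 0.0
        assert row[INCOME_CATEGORIES[:9]].sum() == pytest.approx(75296)
        # and wage categorisation lands merged wages on the same label
        bounds = inc.boundaries.loc["E08000002"].to_numpy()
        codes = assign_income_categories(
            np.array([300.0, 350.0]), np.array(["Employee", "Employee"]), bounds
        )
        assert list(codes) == [2, 2]


class TestAssignIncomeCategories:
    def test_bracketing_against_hand_labels(self):
        bounds = np.array([100.0, 200, 300, 400, 500, 600, 700, 800])
        wages = np.array([50.0, 100.0, 150.0, 799.0, 800.0, 5000.0])
        etype = np.array(["Employee"] * 6)
        codes = assign_income_categories(wages, etype, bounds)
        assert list(codes) == [0, 1, 1, 7, 8, 8]

    def test_non_employees_ignore_wage(self):
        bounds = np.linspace(100, 800, 8)
        codes = assign_income_categories(
            np.array([0.0, 10_000.0]),
            np.array(["Self-employed", "Other"]),
            bounds,
        )
        assert list(codes) == [9, 10]


class TestHarmoniseMissing:
    def _system(self, printed_constraints, printed_baseline):
        zones = printed_baseline.index
        age_sex = ConstraintTable(
            "age_sex",
            pd.DataFrame(
                {"F_16_24": printed_baseline / 2, "M_16_24": printed_baseline / 2},
                index=zones,
            ),
        )
        hh = ConstraintTable(
            "household_type",
            pd.DataFrame(
                {"16_24_dep_n": printed_baseline * 0.6,
                 "16_24_dep_y": printed_baseline * 0.4},
                index=zones,
            ),
        )
        eth = ConstraintTable("ethnicity", printed_constraints["ethnicity"].copy())
        stu = ConstraintTable("student", printed_constraints["student"].copy())
        return {"age_sex": age_sex, "household_type": hh, "ethnicity": eth,
                "student": stu}

    def test_complete_system_passes_through(self, printed_constraints,
                                            printed_baseline):
        h = harmonise_missing(self._system(printed_constraints, printed_baseline))
        assert h.available.all().all()
        assert h.category_maps == {}

    def test_missing_mixed_merges_into_other(self, printed_constraints,
                                             printed_baseline):
        system = self._system(printed_constraints, printed_baseline)
        system["ethnicity"].counts.loc["E08000002", "mixed"] = np.nan
        h = harmonise_missing(system)
        assert h.available.at["E08000002", "ethnicity"]
        assert h.category_maps["ethnicity"]["E08000002"] == {"mixed": "other"}
        # the zone's effective ethnicity system has three usable categories
        row = h.constraints["ethnicity"].counts.loc["E08000002"]
        assert row.notna().sum() == 3

    def test_binary_variable_dropped_per_zone(self, printed_constraints,
                                              printed_baseline):
        system = self._system(printed_constraints, printed_baseline)
        system["student"].counts.loc["E08000003"] = np.nan
        h = harmonise_missing(system)
        assert not h.available.at["E08000003", "student"]
        assert h.available.at["E08000002", "student"]
        assert h.variables_for_zone("E08000003") == [
            "age_sex", "household_type", "ethnicity"
        ]

    def test_minimum_system_runs_on_age_sex_and_household(self,
                                                          printed_constraints,
                                                          printed_baseline):
        system = self._system(printed_constraints, printed_baseline)
        del system["ethnicity"], system["student"]
        h = harmonise_missing(system)
        assert set(h.constraints) == {"age_sex", "household_type"}

    def test_missing_age_sex_is_fatal(self, printed_constraints,
                                      printed_baseline):
        system = self._system(printed_constraints, printed_baseline)
        system["age_sex"].counts.loc["E08000002"] = np.nan
        with pytest.raises(ValueError, match="age_sex"):
            harmonise_missing(system)

    def test_audit_layout_counts_zones_per_variable(self):
        m2008 = pd.DataFrame(
            {"age_sex": [True, True], "student": [True, False]},
            index=["A", "B"],
        )
        m2009 = pd.DataFrame(
            {"age_sex": [True, True], "student": [True, True]},
            index=["A", "B"],
        )
        table = audit_availability({2008: m2008, 2009: m2009})
        assert table.loc[2008, "student"] == 1
        assert table.loc[2009, "student"] == 2
        assert (table["age_sex"] == 2).all()
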