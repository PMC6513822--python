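"""Tests of the synthetic world generator: determinism, conservation of
marginals, and agreement of the stochastic components with closed forms."""

import numpy as np
import pandas as pd
import pytest

from spendsim.categories import (
    AGE_SEX_ADULT,
    AGE_SEX_CHILD,
    EMPLOYMENT_TYPE,
    ETHNICITY,
    HOUSEHOLD_BY_AGE_BAND,
    STUDENT,
    UNEMPLOYMENT,
)
from spendsim.constraints import PERCENTILE_COLUMNS
from spendsim.synthetic_data import (
    ExpenditureModelSpec,
    default_config,
    generate_population,
    generate_world,
    sample_survey,
    tabulate_constraints,
)


def degenerate_config(n_adults=100, survey_size=None, **kwargs):
    """All attribute distributions concentrated on a single category."""
    cfg = default_config(
        n_zones=1,
        mean_adults=n_adults,
        mean_children=20,
        survey_size=survey_size or 450,
        seed=0,
        **kwargs,
    )
    cfg.adult_populations = np.array([n_adults])
    cfg.child_populations = np.array([20])
    for var, probs in cfg.attribute_distributions.items():
        p = probs.copy()
        p.iloc[:, :] = 0.0
        p.iloc[:, 0] = 1.0
        cfg.attribute_distributions[var] = p
    for band, probs in cfg.household_conditional.items():
        p = probs.copy()
        p.iloc[:, :] = 0.0
        p.iloc[:, 0] = 1.0
        cfg.household_conditional[band] = p
    return cfg


class TestGeneratePopulation:
    def test_degenerate_distributions_yield_identical_records(self):
        cfg = degenerate_config()
        pop, _ = generate_population(cfg)
        adults = pop[pop["is_adult"]]
        assert len(adults) == 100
        for var in ("age_sex", "ethnicity", "student", "unemployment"):
            assert adults[var].nunique() == 1

    def test_seeded_generation_is_reproducible(self):
        w1 = generate_world(n_zones=3, mean_adults=200, mean_children=40,
                            survey_size=450, seed=42)
        w2 = generate_world(n_zones=3, mean_adults=200, mean_children=40,
                            survey_size=450, seed=42)
        pd.testing.assert_frame_equal(w1.population, w2.population)
        pd.testing.assert_frame_equal(w1.microdata, w2.microdata)
        pd.testing.assert_frame_equal(w1.diary, w2.diary)
        assert w1.microdata.to_csv() == w2.microdata.to_csv()

    def test_student_share_within_binomial_error(self):
        cfg = default_config(n_zones=1, mean_adults=10_000, mean_children=100,
                             survey_size=450, seed=7)
        p = cfg.attribute_distributions["student"].copy()
        p["student"] = 0.3
        p["not_student"] = 0.7
        cfg.attribute_distributions["student"] = p
        pop, _ = generate_population(cfg)
        adults = pop[pop["is_adult"]]
        n = len(adults)
        count = (adults["student"] == "student").sum()
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(count - 0.3 * n) <= 3 * sd

    def test_invalid_distribution_rejected_with_location(self):
        cfg = default_config(n_zones=2, mean_adults=100, mean_children=20,
                             survey_size=450, seed=0)
        bad = cfg.attribute_distributions["ethnicity"].copy()
        bad.iloc[1, 0] += 0.5
        cfg.attribute_distributions["ethnicity"] = bad
        with pytest.raises(ValueError, match="ethnicity"):
            generate_population(cfg)

    def test_household_types_respect_age_bands(self, tiny_world):
        adults = tiny_world.population[tiny_world.population["is_adult"]]
        for band, allowed in HOUSEHOLD_BY_AGE_BAND.items():
            sub = adults[adults["age_sex"].str.endswith(band)]
            assert set(sub["household_type"]) <= set(allowed)


class TestConservation:
    """Emitted constraint marginals must be exactly the marginals of the
    simulated true population."""

    def test_constraints_match_population_tables(self, tiny_world):
        truth = tiny_world.ground_truth.true_population_tables
        bundle = tiny_world.constraints
        for var in ("age_sex", "ethnicity", "student", "unemployment",
                    "household_type"):
            pd.testing.assert_frame_equal(
                bundle.raw[var].counts, truth[var], check_names=False
            )
        pd.testing.assert_frame_equal(
            bundle.child_age_sex.counts, truth["age_sex_child"], check_names=False
        )

    def test_every_constraint_row_sums_to_zone_population(self, tiny_world):
        pops = (
            tiny_world.population[tiny_world.population["is_adult"]]
            .groupby("zone_code")
            .size()
            .astype(float)
        )
        for var in ("age_sex", "ethnicity", "student", "unemployment",
                    "household_type"):
            sums = tiny_world.constraints.raw[var].row_totals()
            pd.testing.assert_series_equal(sums, pops, check_names=False)

    def test_midyear_minus_communal_recovers_household_counts(self, tiny_world):
        b = tiny_world.constraints
        pd.testing.assert_frame_equal(
            b.midyear_adult - b.communal_adult, b.raw["age_sex"].counts
        )

    def test_single_person_population_has_one_nonzero_cell(self):
        cfg = degenerate_config(n_adults=1)
        pop, _ = generate_population(cfg)
        bundle = tabulate_constraints(pop, cfg)
        for var in ("age_sex", "ethnicity", "student", "unemployment"):
            counts = bundle.raw[var].counts.to_numpy()
            assert (counts > 0).sum() == 1
            assert counts.sum() == 1


class TestWageQuantiles:
    def test_percentile_boundaries_match_sort_based_oracle(self, tiny_world):
        adults = tiny_world.population[tiny_world.population["is_adult"]]
        earnings = tiny_world.constraints.earnings.set_index("zone_code")
        zone = earnings.index[0]
        wages = np.sort(
            adults.loc[
                (adults["zone_code"] == zone)
                & (adults["employment_type"] == "Employee"),
                "gross_weekly_wage",
            ].to_numpy()
        )
        # linear interpolation between order statistics, manually
        for k, col in enumerate(PERCENTILE_COLUMNS, start=1):
            q = k / 10.0
            h = (len(wages) - 1) * q
            lo = int(np.floor(h))
            expected = wages[lo] + (h - lo) * (wages[min(lo + 1, len(wages) - 1)] - wages[lo])
            assert earnings.at[zone, col] == pytest.approx(expected, rel=1e-12)

    def test_employment_counts_partition_adults(self, tiny_world):
        earnings = tiny_world.constraints.earnings
        adults = tiny_world.population[tiny_world.population["is_adult"]]
        total = earnings[["employees", "self_employed", "other"]].sum(axis=1)
        pops = adults.groupby("zone_code").size().to_numpy()
        assert (total.to_numpy() == pops).all()


class TestSampleSurvey:
    def test_zero_noise_zero_effects_diary_equals_baseline(self):
        cfg = degenerate_config(n_adults=500, survey_size=450)
        cfg.apply_regional_prices = False
        model = cfg.expenditure_model
        cfg.expenditure_model = ExpenditureModelSpec(
            categories=model.categories,
            baseline=model.baseline,
            effects={},
            sigma={c: 0.0 for c in model.categories},
            participation={c: 1.0 for c in model.categories},
        )
        pop, truth = generate_population(cfg)
        micro, diary = sample_survey(pop, cfg)
        for code in model.categories:
            vals = diary.loc[diary["coicop"] == code, "weekly_expenditure_gbp"]
            assert np.allclose(vals, model.baseline[code])

    def test_zero_effects_truth_identical_across_zones(self):
        cfg = default_config(n_zones=4, mean_adults=300, mean_children=60,
                             survey_size=450, seed=5)
        cfg.apply_regional_prices = False
        cfg.adult_populations = np.full(4, 300)
        cfg.child_populations = np.full(4, 60)
        model = cfg.expenditure_model
        cfg.expenditure_model = ExpenditureModelSpec(
            categories=model.categories,
            baseline=model.baseline,
            effects={},
            sigma={c: 0.0 for c in model.categories},
            participation={c: 1.0 for c in model.categories},
        )
        _, truth = generate_population(cfg)
        per_zone = truth.true_zone_expenditure
        assert np.allclose(per_zone.to_numpy(), per_zone.to_numpy()[0], rtol=1e-12)

    def test_zone_label_absent_from_microdata(self, tiny_world):
        assert "zone_code" not in tiny_world.microdata.columns
        assert "region" in tiny_world.microdata.columns

    def test_resample_with_fixed_seed_is_identical(self, tiny_world):
        m2, d2 = sample_survey(tiny_world.population, tiny_world.config)
        pd.testing.assert_frame_equal(tiny_world.microdata, m2)
        pd.testing.assert_frame_equal(tiny_world.diary, d2)

    def test_oversized_survey_rejected(self):
        cfg = degenerate_config(n_adults=100, survey_size=100_000)
        pop, _ = generate_population(cfg)
        cfg2 = cfg
        with pytest.raises(ValueError, match="survey_size"):
            sample_survey(pop, cfg2)

    def test_diary_mean_matches_lognormal_closed_form(self):
        # one zone, large survey: mean of exp(log b + s N(0,1)) is
        # b * exp(s^2 / 2); participation scales it
        cfg = degenerate_config(n_adults=12_000, survey_size=10_000)
        cfg.apply_regional_prices = False
        code = cfg.expenditure_model.categories[0]
        b = cfg.expenditure_model.baseline[code]
        s = 0.6
        cfg.expenditure_model = ExpenditureModelSpec(
            categories=[code],
            baseline={code: b},
            effects={},
            sigma={code: s},
            participation={code: 1.0},
        )
        pop, _ = generate_population(cfg)
        micro, diary = sample_survey(pop, cfg)
        vals = diary.loc[diary["coicop"] == code, "weekly_expenditure_gbp"]
        expected = b * np.exp(s**2 / 2)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) <= 2 * se

    def test_pool_adequacy_floor_enforced(self):
        with pytest.raises(ValueError, match="sampling-pool"):
            default_config(n_zones=2, mean_adults=300, mean_children=50,
                           survey_size=100, seed=0).validate()


class TestDeprivationRank:
    def test_rank_orientation_low_is_deprived(self, tiny_world):
        adults = tiny_world.population[tiny_world.population["is_adult"]]
        unemp = (
            adults.assign(u=(adults["unemployment"] == "unemployed"))
            .groupby("zone_code")["u"]
            .mean()
        )
        ranks = tiny_world.deprivation.set_index("zone_code")["rank"]
        # most-unemployed zone must get the lowest rank
        assert ranks.idxmin() == unemp.idxmax()
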