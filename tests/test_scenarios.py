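"""Scenario transformations, the pipeline driver and the trend runner."""

import numpy as np
import pandas as pd
import pytest

from nutrinet import (
    ScenarioConfig,
    animal_source_weights,
    apply_scenario,
    repurpose_feed,
    run_pipeline,
    run_trend,
)
from nutrinet.errors import ConfigurationError
from nutrinet.foods import GRAIN_FORMS
from nutrinet.scenarios import SCENARIOS


def constant_over_years(data):
    """Copy of *data* with every year repeating the first year's values."""
    out = data.copy()
    y0 = out.years[0]
    plans = [
        ("production", ["crop", "region"], ["tonnes"]),
        ("trade", ["crop"], ["imports", "exports", "stock_change"]),
        ("use", ["crop"], ["feed", "seed", "other"]),
        ("population", ["region"], ["population"]),
        ("structure", ["region", "age_group", "sex"], ["proportion"]),
    ]
    for name, keys, vals in plans:
        df = getattr(out, name)
        base = df[df["year"] == y0][keys + vals]
        merged = df.drop(columns=vals).merge(base, on=keys, how="left")
        setattr(out, name, merged[list(df.columns)])
    return out


class TestScenarioConfig:
    def test_presets_cover_the_five_scenarios(self):
        assert set(SCENARIOS) == {"S1", "S2a", "S2b", "S3a", "S3b"}
        s3b = SCENARIOS["S3b"]
        assert s3b.intl_trade == "none" and s3b.nonfood_use == "none"
        assert s3b.animal_foods == "none" and s3b.oilseeds_as_seed
        assert s3b.aggregation == "provincial" and not s3b.interprov_trade

    def test_contradicting_a_preset_is_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(id="S1", flw_multiplier=0.5)

    def test_unknown_id_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig.from_id("S9")


class TestApplyScenario:
    def test_s2a_halves_every_loss_fraction(self, small_data):
        out = apply_scenario(small_data, SCENARIOS["S2a"])
        assert np.allclose(out.losses["fraction"], small_data.losses["fraction"] * 0.5)

    def test_wholegrain_replacement_moves_a_tenth_of_the_refined_stream(self, small_data):
        data = small_data.copy()
        for grain in GRAIN_FORMS:
            data.processing.wholegrain_fraction[grain] = 0.0
        out = apply_scenario(data, SCENARIOS["S2a"])
        for grain in GRAIN_FORMS:
            assert out.processing.wholegrain_fraction[grain] == pytest.approx(0.10)
        # with a nonzero current share w the transfer gives w + 0.1*(1-w)
        out2 = apply_scenario(small_data, SCENARIOS["S2a"])
        w = small_data.processing.wholegrain_fraction["rice"]
        assert out2.processing.wholegrain_fraction["rice"] == pytest.approx(w + 0.1 * (1 - w))

    def test_s3a_zeroes_trade_feed_other_and_animal_but_keeps_seed(self, small_data):
        out = apply_scenario(small_data, SCENARIOS["S3a"])
        assert (out.trade[["imports", "exports", "stock_change"]] == 0).all().all()
        assert (out.use["feed"] == 0).all()
        assert (out.use["other"] == 0).all()
        pd.testing.assert_series_equal(out.use["seed"], small_data.use["seed"])
        assert (out.animal_intake["grams_per_capita_day"] == 0).all()

    def test_s2b_reduces_red_meat_and_frees_feed(self, small_data):
        out = apply_scenario(small_data, SCENARIOS["S2b"])
        before = small_data.animal_intake.set_index("food_group")["grams_per_capita_day"]
        after = out.animal_intake.set_index("food_group")["grams_per_capita_day"]
        assert after["red_meat"] == pytest.approx(before["red_meat"] * 0.55)
        assert after.drop("red_meat").equals(before.drop("red_meat"))
        feed_before = small_data.use.set_index("crop")["feed"]
        feed_after = out.use.set_index("crop")["feed"]
        maize = feed_after.loc["maize"] / feed_before.loc["maize"]
        assert np.allclose(maize, 0.55)  # share 1.0, reduction 0.45
        assert feed_after.loc["apple"].sum() == pytest.approx(feed_before.loc["apple"].sum())


class TestRepurposeFeed:
    def test_zero_reduction_frees_nothing(self):
        feed = pd.Series({"maize": 1000.0, "apple": 10.0})
        assert (repurpose_feed(feed, 0.0) == 0).all()

    def test_linear_rule(self):
        feed = pd.Series({"maize": 1000.0})
        assert repurpose_feed(feed, 0.45)["maize"] == pytest.approx(450.0)

    def test_nonfeed_crops_untouched(self):
        feed = pd.Series({"apple": 500.0})
        assert repurpose_feed(feed, 0.45)["apple"] == 0.0

    def test_invalid_share_rejected(self):
        with pytest.raises(ConfigurationError):
            repurpose_feed(pd.Series({"maize": 1.0}), 0.5, shares={"maize": 1.5})


class TestAnimalSourceWeights:
    def test_zero_intakes_give_zero_weights(self, small_data):
        intakes = small_data.animal_intake.assign(grams_per_capita_day=0.0)
        mu = pd.Series({n: 1.0 for n in small_data.animal_composition["nutrient"].unique()})
        w = animal_source_weights(intakes, small_data.animal_composition, mu, 100.0)
        assert (w == 0).all()

    def test_population_cancels_for_per_capita_requirements(self):
        intakes = pd.DataFrame({"food_group": ["red_meat"], "grams_per_capita_day": [100.0]})
        contents = pd.DataFrame(
            {"food_group": ["red_meat"], "nutrient": ["iron"], "content": [0.01]}
        )
        for pop in (10.0, 1e6):
            mu = pd.Series({"iron": 2.0 * pop})  # per-capita requirement 2 units/day
            w = animal_source_weights(intakes, contents, mu, pop)
            assert w["iron"] == pytest.approx(0.5)


class TestPipeline:
    def test_s1_reproduces_generator_ground_truth(self, small_config, small_data, small_truth):
        results = run_pipeline(small_data, "S1", years=small_config.years)
        truth = small_truth[small_truth["scenario"] == "S1"]
        merged = truth.merge(
            results,
            on=["region", "year", "nutrient", "reference"],
            suffixes=("_truth", "_pipe"),
        )
        assert len(merged) == len(truth)
        rel_cov = ((merged["coverage_truth"] - merged["coverage_pipe"]).abs()
                   / merged["coverage_truth"])
        rel_div = ((merged["diversity_truth"] - merged["diversity_pipe"]).abs()
                   / merged["diversity_truth"])
        assert rel_cov.max() <= 1e-9 and rel_div.max() <= 1e-9
        assert (merged["band_truth"] == merged["band_pipe"]).all()

    def test_loss_halving_strictly_increases_every_coverage(self, small_data):
        year = small_data.years[-1]
        s1 = run_pipeline(small_data, "S1", years=[year])
        s2a = run_pipeline(small_data, "S2a", years=[year])
        key = ["nutrient", "reference"]
        merged = s1.merge(s2a, on=key, suffixes=("_1", "_2"))
        assert (merged["coverage_2"] > merged["coverage_1"]).all()

    def test_s3a_drops_animal_only_nutrients_to_zero(self, small_data):
        """A nutrient supplied only by animal foods vanishes without the animal node."""
        data = small_data.copy()
        data.composition.loc[data.composition["nutrient"] == "riboflavin", "content"] = 0.0
        year = data.years[-1]
        s1 = run_pipeline(data, "S1", years=[year]).set_index(["nutrient", "reference"])
        s3 = run_pipeline(data, "S3a", years=[year]).set_index(["nutrient", "reference"])
        assert s1.loc[("riboflavin", "EAR"), "coverage"] > 0
        assert s3.loc[("riboflavin", "EAR"), "coverage"] == 0.0
        assert np.isnan(s3.loc[("riboflavin", "EAR"), "diversity"])

    def test_single_region_provincial_run_equals_national_run(self, national_data):
        year = national_data.years[-1]
        s3a = run_pipeline(national_data, "S3a", years=[year])
        s3b = run_pipeline(national_data, "S3b", years=[year])
        key = ["nutrient", "reference"]
        merged = s3a.merge(s3b, on=key, suffixes=("_a", "_b"))
        assert np.allclose(merged["coverage_a"], merged["coverage_b"], rtol=1e-12)
        assert np.allclose(merged["diversity_a"], merged["diversity_b"], rtol=1e-12)

    def test_pooling_provinces_recovers_national_coverage(self, small_data):
        """Summed provincial supplies and requirements reproduce national coverage."""
        year = small_data.years[-1]
        _, nets_b = run_pipeline(small_data, "S3b", years=[year], return_networks=True)
        _, nets_a = run_pipeline(small_data, "S3a", years=[year], return_networks=True)
        supply_sum = sum(net["supply"] for net in nets_b.values())
        mu_sum = sum(net["mu"].fillna(0.0) for net in nets_b.values())
        national = nets_a[("national", year)]
        pooled = supply_sum.sum(axis=0) / mu_sum["EAR"].replace(0.0, np.nan)
        direct = national["supply"].sum(axis=0) / national["mu"]["EAR"].replace(0.0, np.nan)
        pd.testing.assert_series_equal(
            pooled.dropna(), direct.dropna(), rtol=1e-9, check_names=False
        )

    def test_missing_year_is_a_data_error(self, small_data):
        from nutrinet.errors import DataError

        with pytest.raises(DataError):
            run_pipeline(small_data, "S1", years=[1890])


class TestTrend:
    def test_constant_inputs_give_a_flat_trend(self, small_data):
        data = constant_over_years(small_data)
        trend = run_trend(data)
        spread = trend.groupby(["nutrient", "reference"])["coverage"].agg(["min", "max"])
        assert np.allclose(spread["min"], spread["max"], rtol=1e-12)

    def test_doubling_supply_masses_doubles_coverage_not_diversity(self, small_data):
        data = constant_over_years(small_data)
        y0, y1 = data.years[0], data.years[-1]
        for name, cols in [
            ("production", ["tonnes"]),
            ("trade", ["imports", "exports", "stock_change"]),
            ("use", ["feed", "seed", "other"]),
        ]:
            frame = getattr(data, name)
            frame.loc[frame["year"] == y1, cols] *= 2.0
        trend = run_trend(data).set_index(["year", "nutrient", "reference"])
        for (nutrient, ref), _ in trend.groupby(["nutrient", "reference"]):
            first = trend.loc[(y0, nutrient, ref)]
            last = trend.loc[(y1, nutrient, ref)]
            assert last["coverage"] == pytest.approx(2 * first["coverage"], rel=1e-9)
            assert last["diversity"] == pytest.approx(first["diversity"], rel=1e-9)

    def test_growing_population_with_fixed_supply_decreases_coverage(self, small_data):
        data = constant_over_years(small_data)
        y1 = data.years[-1]
        mask = data.population["year"] == y1
        data.population.loc[mask, "population"] *= 1.2
        trend = run_trend(data)
        wide = trend.pivot_table(index=["nutrient", "reference"], columns="year", values="coverage")
        assert (wide[y1] < wide[data.years[0]]).all()
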