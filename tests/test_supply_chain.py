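"""Supply-chain accounting: worked balances, processing splits, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrinet import ProcessingSpec, food_supply, split_and_process, vegetable_subgroup_supply
from nutrinet.errors import ConfigurationError, DataError, DomainError
from nutrinet.foods import TONNES_YEAR_TO_G_DAY, VEG_SUBGROUPS
from nutrinet.supply_chain import crop_nutrient_supply

ZERO7 = np.zeros(7)


class TestFoodSupply:
    @pytest.mark.parametrize(
        "p,f,beta,losses,alpha,expected",
        [
            (0.0, 0.0, 0.0, ZERO7, 1.0, 0.0),
            # 365 t/yr of pure imports with no losses is 1e6 g/day
            (0.0, 365.0, 0.0, ZERO7, 1.0, 1_000_000.0),
            # hand-computed balance: (1000*0.9^3 + 71 - 300)*0.8*1e6/365
            (1000.0, 71.0, 300.0, np.array([0.1, 0.1, 0.1, 0, 0, 0, 0]), 0.8,
             (1000 * 0.9**3 + 71 - 300) * 0.8 * 1e6 / 365),
        ],
    )
    def test_worked_balances(self, p, f, beta, losses, alpha, expected):
        assert food_supply(p, f, beta, losses, alpha) == pytest.approx(expected, rel=1e-12)

    def test_negative_balance_clamped_with_diagnostic(self):
        diags = []
        out = food_supply(10.0, 0.0, 100.0, ZERO7, 1.0, diagnostics=diags, label="x")
        assert out == 0.0
        assert len(diags) == 1 and diags[0]["bracket_tonnes"] == pytest.approx(-90.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"loss_fractions": np.array([1.0, 0, 0, 0, 0, 0, 0])},
            {"loss_fractions": np.full(7, -0.1)},
            {"loss_fractions": ZERO7, "edible_proportion": 0.0},
            {"loss_fractions": ZERO7, "edible_proportion": 1.5},
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            food_supply(1.0, 0.0, 0.0, **kwargs)

    @given(
        p=st.floats(0, 1e6),
        f=st.floats(-1e5, 1e5),
        losses=st.lists(st.floats(0, 0.6), min_size=7, max_size=7),
    )
    def test_reducing_any_loss_never_decreases_supply(self, p, f, losses):
        losses = np.array(losses)
        base = food_supply(p, f, 0.0, losses, 0.9)
        for h in range(7):
            lower = losses.copy()
            lower[h] *= 0.5
            assert food_supply(p, f, 0.0, lower, 0.9) >= base - 1e-9 * max(base, 1.0)

    @given(p=st.floats(0, 1e6), c=st.floats(0.1, 10))
    def test_linearity_in_production(self, p, c):
        losses = np.array([0.1, 0.05, 0.02, 0.1, 0.02, 0.03, 0.08])
        assert food_supply(c * p, 0.0, 0.0, losses, 0.8) == pytest.approx(
            c * food_supply(p, 0.0, 0.0, losses, 0.8), rel=1e-12
        )

    def test_halving_all_losses_scales_by_loss_ratio(self):
        losses = np.array([0.1, 0.08, 0.06, 0.12, 0.05, 0.04, 0.15])
        base = food_supply(500.0, 20.0, 30.0, losses, 0.9)
        halved = food_supply(500.0, 20.0, 30.0, losses / 2, 0.9)
        # the bracket mixes p-and-f terms, so compare against a loop oracle
        bracket = 500.0 * np.prod(1 - losses[:3]) + 20.0 - 30.0
        bracket_h = 500.0 * np.prod(1 - losses[:3] / 2) + 20.0 - 30.0
        expected_ratio = (bracket_h / bracket) * np.prod(1 - losses[3:] / 2) / np.prod(1 - losses[3:])
        assert halved / base == pytest.approx(expected_ratio, rel=1e-12)
        assert halved > base


class TestVegetableDisaggregation:
    losses = np.array([0.1, 0.05, 0.05, 0.08, 0.04, 0.03, 0.1])

    def _shares(self, values):
        return dict(zip(VEG_SUBGROUPS, values))

    def _uniform(self, vec, alpha=0.9):
        return {s: vec for s in VEG_SUBGROUPS}, {s: alpha for s in VEG_SUBGROUPS}

    def test_degenerate_share_equals_single_crop_balance(self):
        sub_losses, sub_alpha = self._uniform(self.losses)
        out = vegetable_subgroup_supply(
            1000.0, 50.0, 100.0, self.losses,
            self._shares([1, 0, 0, 0, 0, 0, 0]), sub_losses, sub_alpha,
        )
        direct = food_supply(1000.0, 50.0, 100.0, self.losses, 0.9)
        assert out.iloc[0] == pytest.approx(direct, rel=1e-12)
        assert (out.iloc[1:] == 0).all()

    def test_equal_shares_split_total_evenly(self):
        sub_losses, sub_alpha = self._uniform(self.losses)
        out = vegetable_subgroup_supply(
            700.0, 0.0, 0.0, self.losses, self._shares([1 / 7] * 7), sub_losses, sub_alpha
        )
        total = food_supply(700.0, 0.0, 0.0, self.losses, 0.9)
        assert np.allclose(out, total / 7, rtol=1e-12)

    def test_distinct_alphas_match_loop_oracle(self):
        shares = [0.3, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05]
        alphas = [0.6, 0.7, 0.8, 0.9, 0.95, 0.85, 0.75]
        sub_losses = {s: self.losses for s in VEG_SUBGROUPS}
        sub_alpha = dict(zip(VEG_SUBGROUPS, alphas))
        out = vegetable_subgroup_supply(
            2000.0, 100.0, 300.0, self.losses, self._shares(shares), sub_losses, sub_alpha
        )
        bracket = 2000.0 * np.prod(1 - self.losses[:3]) + 100.0 - 300.0
        for sub, theta, alpha in zip(VEG_SUBGROUPS, shares, alphas):
            expected = bracket * theta * np.prod(1 - self.losses[3:]) * TONNES_YEAR_TO_G_DAY * alpha
            assert out[sub] == pytest.approx(expected, rel=1e-12)

    def test_bad_share_sum_rejected(self):
        sub_losses, sub_alpha = self._uniform(self.losses)
        with pytest.raises(DataError):
            vegetable_subgroup_supply(
                100.0, 0.0, 0.0, self.losses,
                self._shares([0.5, 0.1, 0.1, 0.1, 0.05, 0.05, 0.0]), sub_losses, sub_alpha,
            )


class TestSplitAndProcess:
    def spec(self, **overrides):
        base = dict(
            wholegrain_fraction={"rice": 0.0, "wheat": 0.0},
            food_oil_fraction={"soybean": 0.5, "groundnut": 0.0, "sesame_seed": 0.3},
            extraction_rate={
                "soybean": 0.16, "groundnut": 0.4, "sesame_seed": 0.45,
                "sunflower_seed": 0.4, "linseed": 0.33, "rapeseed": 0.38,
            },
            shelling_rate={"groundnut": 0.7},
            form_edible={},
        )
        base.update(overrides)
        return ProcessingSpec(**base)

    def test_zero_wholegrain_fraction_routes_all_to_refined(self):
        out = split_and_process({"rice": 100.0}, self.spec())
        assert out["brown_rice"] == 0.0
        assert out["refined_rice"] == pytest.approx(100.0)

    def test_groundnut_oil_applies_shelling_then_extraction(self):
        out = split_and_process({"groundnut": 1000.0}, self.spec())
        assert out["groundnut_oil"] == pytest.approx(1000 * 0.7 * 0.4)

    def test_soybean_even_split_between_seed_and_oil_streams(self):
        out = split_and_process({"soybean": 200.0}, self.spec())
        assert out["soybean"] == pytest.approx(100.0)
        assert out["soybean_oil"] == pytest.approx(100.0 * 0.16)

    def test_oilseeds_as_seed_routes_everything_to_seed_consumption(self):
        out = split_and_process(
            {"sunflower_seed": 50.0, "soybean": 80.0}, self.spec(), oilseeds_as_seed=True
        )
        assert out["sunflower_seed"] == pytest.approx(50.0)
        assert out["sunflower_oil"] == 0.0
        assert out["soybean"] == pytest.approx(80.0)

    def test_unknown_crop_rejected(self):
        with pytest.raises(ConfigurationError):
            split_and_process({"apple": 10.0}, self.spec())

    @given(
        mass=st.floats(0, 1e6),
        w=st.floats(0, 1),
        phi=st.floats(0, 1),
        alpha=st.floats(0.1, 1),
    )
    def test_mass_conservation(self, mass, w, phi, alpha):
        spec = self.spec(
            wholegrain_fraction={"rice": w, "wheat": w},
            food_oil_fraction={"soybean": phi, "groundnut": phi, "sesame_seed": phi},
            form_edible={"brown_rice": alpha, "refined_rice": alpha, "soybean": alpha},
        )
        out = split_and_process({"rice": mass, "soybean": mass, "linseed": mass}, spec)
        assert out["brown_rice"] + out["refined_rice"] <= mass * (1 + 1e-12)
        assert out["soybean"] + out["soybean_oil"] <= mass * (1 + 1e-12)
        assert out["linseed_oil"] <= mass * (1 + 1e-12)

    def test_conservation_is_equality_when_alpha_and_extraction_are_one(self):
        spec = self.spec(
            wholegrain_fraction={"rice": 0.3, "wheat": 0.0},
            extraction_rate={"soybean": 1.0, "groundnut": 1.0, "sesame_seed": 1.0,
                             "sunflower_seed": 1.0, "linseed": 1.0, "rapeseed": 1.0},
            shelling_rate={},
            food_oil_fraction={"soybean": 0.4, "groundnut": 0.0, "sesame_seed": 0.3},
        )
        out = split_and_process({"rice": 10.0, "soybean": 10.0}, spec)
        assert out["brown_rice"] + out["refined_rice"] == pytest.approx(10.0, rel=1e-12)
        assert out["soybean"] + out["soybean_oil"] == pytest.approx(10.0, rel=1e-12)


class TestCropNutrientSupply:
    def contents(self, rows):
        return pd.DataFrame(rows, columns=["form", "nutrient", "content"])

    def test_single_form_direct_arithmetic(self):
        table = self.contents([("apple", "iron", 0.5)])
        out = crop_nutrient_supply({"apple": 100.0}, table)
        assert out.loc["apple", "iron"] == pytest.approx(50.0)

    def test_zero_retention_annihilates_a_nutrient(self):
        table = self.contents([("apple", "iron", 0.5), ("apple", "zinc", 0.2)])
        out = crop_nutrient_supply({"apple": 100.0}, table, retention={("apple", "iron"): 0.0})
        assert out.loc["apple", "iron"] == 0.0
        assert out.loc["apple", "zinc"] == pytest.approx(20.0)

    def test_processed_forms_fold_back_onto_their_source(self):
        table = self.contents([("brown_rice", "iron", 1.0), ("refined_rice", "iron", 2.0)])
        out = crop_nutrient_supply({"brown_rice": 60.0, "refined_rice": 40.0}, table)
        assert list(out.index) == ["rice"]
        assert out.loc["rice", "iron"] == pytest.approx(140.0)

    def test_missing_content_row_names_the_form(self):
        with pytest.raises(DataError, match="banana"):
            crop_nutrient_supply({"banana": 1.0}, self.contents([("apple", "iron", 0.1)]))

    @given(s=st.floats(0, 1e4), c=st.floats(0.1, 10))
    def test_linearity_in_supply(self, s, c):
        table = self.contents([("apple", "iron", 0.37)])
        a = crop_nutrient_supply({"apple": s}, table).loc["apple", "iron"]
        b = crop_nutrient_supply({"apple": c * s}, table).loc["apple", "iron"]
        assert b == pytest.approx(c * a, rel=1e-12, abs=1e-12)
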