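"""Food-system scenarios and the coverage/diversity pipeline driver.

Five scenarios adjust the plant-based food supply relative to the baseline:

========  ==========================================================
S1        Baseline: current losses, trade, uses, animal-based foods.
S2a       Direct-loss reduction: food loss and waste halved at every
          stage; 10% of the refined rice/wheat streams shifted to
          whole grains.
S2b       As S2a, plus red-meat intake reduced by 45% and the
          correspondingly freed feed crops repurposed for food.
S3a       National self-sufficiency: no international trade, no feed
          or other non-food use (seed still sown), no animal-based
          foods, oilseeds consumed as seeds; S2a efficiency retained.
S3b       As S3a per province, without inter-provincial trade.
========  ==========================================================

``run_pipeline`` orchestrates supply-chain accounting, requirement
aggregation and network metrics into a tidy results table; ``run_trend``
is the multi-year plant-food-only driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import metrics, requirements, supply_chain
from .datasets import FoodSystemDataset
from .errors import ConfigurationError, DataError
from .foods import (
    ANIMAL_NODE,
    GRAIN_FORMS,
    PROCESSABLE,
    PRODUCTION_IDS,
    VEG_SUBGROUPS,
    VEGETABLES_TOTAL,
    references_for,
)

logger = logging.getLogger(__name__)

#: Crops whose feed use is tied to red-meat production (freed pro rata
#: when red-meat intake drops); overridable per call.
DEFAULT_FEED_CROP_SHARES = {"maize": 1.0, "soybean": 1.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Switch set defining one scenario (see module docstring)."""

    id: str = "custom"
    flw_multiplier: float = 1.0
    wholegrain_replacement: float = 0.0
    red_meat_reduction: float = 0.0
    feed_repurpose: str = "none"  # none | partial | full
    nonfood_use: str = "current"  # current | none
    intl_trade: str = "current"  # current | none
    interprov_trade: bool = True
    animal_foods: str = "current"  # current | reduced | none
    oilseeds_as_seed: bool = False
    aggregation: str = "national"  # national | provincial

    def __post_init__(self):
        if self.feed_repurpose not in ("none", "partial", "full"):
            raise ConfigurationError(f"feed_repurpose {self.feed_repurpose!r} invalid")
        if self.nonfood_use not in ("current", "none"):
            raise ConfigurationError(f"nonfood_use {self.nonfood_use!r} invalid")
        if self.intl_trade not in ("current", "none"):
            raise ConfigurationError(f"intl_trade {self.intl_trade!r} invalid")
        if self.animal_foods not in ("current", "reduced", "none"):
            raise ConfigurationError(f"animal_foods {self.animal_foods!r} invalid")
        if self.aggregation not in ("national", "provincial"):
            raise ConfigurationError(f"aggregation {self.aggregation!r} invalid")
        if not 0.0 < self.flw_multiplier <= 1.0:
            raise ConfigurationError("flw_multiplier must lie in (0, 1]")
        if not 0.0 <= self.wholegrain_replacement <= 1.0:
            raise ConfigurationError("wholegrain_replacement must lie in [0, 1]")
        if not 0.0 <= self.red_meat_reduction <= 1.0:
            raise ConfigurationError("red_meat_reduction must lie in [0, 1]")
        preset = SCENARIOS.get(self.id)
        if preset is not None and self != preset:
            raise ConfigurationError(
                f"settings contradict the {self.id} preset; use id='custom' for variants"
            )

    @classmethod
    def from_id(cls, scenario_id: str) -> "ScenarioConfig":
        try:
            return SCENARIOS[scenario_id]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {scenario_id!r}; choose from {sorted(SCENARIOS)}"
            ) from None


def _make_presets() -> dict[str, ScenarioConfig]:
    base = {"flw_multiplier": 0.5, "wholegrain_replacement": 0.10}
    s3 = dict(
        base,
        feed_repurpose="full",
        nonfood_use="none",
        intl_trade="none",
        animal_foods="none",
        oilseeds_as_seed=True,
    )
    presets = {
        "S1": ScenarioConfig(id="S1"),
        "S2a": ScenarioConfig(id="S2a", **base),
        "S2b": ScenarioConfig(
            id="S2b",
            **base,
            red_meat_reduction=0.45,
            feed_repurpose="partial",
            animal_foods="reduced",
        ),
        "S3a": ScenarioConfig(id="S3a", **s3),
        "S3b": ScenarioConfig(
            id="S3b", **s3, interprov_trade=False, aggregation="provincial"
        ),
    }
    return presets


# constructed after the dataclass so __post_init__ can consult it
SCENARIOS: dict[str, ScenarioConfig] = {}
SCENARIOS.update(_make_presets())

#: Plant-food-only configuration used for the multi-year trend.
TREND_CONFIG = ScenarioConfig(id="PFS_trend", animal_foods="none")


def repurpose_feed(
    feed_use: pd.Series,
    red_meat_reduction: float,
    shares: Mapping[str, float] | None = None,
) -> pd.Series:
    """Feed tonnage freed for food use when red-meat intake is reduced.

    ``freed_i = feed_i * share_i * reduction`` with per-crop shares of the
    feed stream attributable to red-meat production (default 1 for the
    designated feed crops, 0 otherwise).
    """
    if (feed_use < 0).any():
        raise DataError("feed use must be non-negative")
    shares = DEFAULT_FEED_CROP_SHARES if shares is None else shares
    for crop, s in shares.items():
        if not 0.0 <= s <= 1.0:
            raise ConfigurationError(f"feed share for {crop} outside [0, 1]")
    share_vec = pd.Series({c: shares.get(c, 0.0) for c in feed_use.index}, dtype=float)
    return feed_use * share_vec * red_meat_reduction


def apply_scenario(
    data: FoodSystemDataset,
    config: ScenarioConfig,
    feed_shares: Mapping[str, float] | None = None,
) -> FoodSystemDataset:
    """Return a transformed copy of *data* reflecting the scenario switches.

    Loss fractions are scaled by the FLW multiplier; a fraction of the
    refined rice/wheat streams moves to whole grain; trade, feed and other
    non-food uses are zeroed per the switches (seed use always remains);
    red-meat-linked feed is partially freed in the ``partial`` mode; animal
    intakes are reduced or zeroed.
    """
    out = data.copy()
    out.losses["fraction"] = out.losses["fraction"] * config.flw_multiplier
    if config.wholegrain_replacement > 0:
        r = config.wholegrain_replacement
        for grain in GRAIN_FORMS:
            w = out.processing.wholegrain_fraction.get(grain, 0.0)
            out.processing.wholegrain_fraction[grain] = w + r * (1.0 - w)
    if config.intl_trade == "none":
        out.trade[["imports", "exports", "stock_change"]] = 0.0
    if config.nonfood_use == "none":
        out.use["other"] = 0.0
    if config.feed_repurpose == "full":
        out.use["feed"] = 0.0
    elif config.feed_repurpose == "partial":
        shares = DEFAULT_FEED_CROP_SHARES if feed_shares is None else feed_shares
        for crop, s in shares.items():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"feed share for {crop} outside [0, 1]")
        share_vec = out.use["crop"].map(lambda c: shares.get(c, 0.0))
        out.use["feed"] = out.use["feed"] * (1.0 - share_vec * config.red_meat_reduction)
    if config.animal_foods == "none":
        out.animal_intake["grams_per_capita_day"] = 0.0
    elif config.animal_foods == "reduced":
        mask = out.animal_intake["food_group"] == "red_meat"
        out.animal_intake.loc[mask, "grams_per_capita_day"] *= 1.0 - config.red_meat_reduction
    return out


def animal_source_weights(
    intakes: pd.DataFrame,
    contents: pd.DataFrame,
    mu: pd.Series,
    population: float,
) -> pd.Series:
    """Edge weights of the aggregated animal-source node, per nutrient.

    ``W_animal,j = pop * sum_g intake_g * content_gj / mu_j``; per-capita
    requirements would cancel the population, so the weight is invariant to
    population size for fixed per-capita intakes.
    """
    wide = contents.pivot(index="food_group", columns="nutrient", values="content")
    intake = intakes.set_index("food_group")["grams_per_capita_day"]
    missing = [g for g in intake.index if g not in wide.index]
    if missing:
        raise DataError(f"no animal-food composition for groups {missing}")
    per_capita = wide.mul(intake, axis=0).sum(axis=0)
    return metrics.edge_weights(per_capita * population, mu.reindex(per_capita.index))


def animal_nutrient_supply(
    intakes: pd.DataFrame, contents: pd.DataFrame, population: float
) -> pd.Series:
    """Total nutrient supply (units/day) of the aggregated animal node."""
    wide = contents.pivot(index="food_group", columns="nutrient", values="content")
    intake = intakes.set_index("food_group")["grams_per_capita_day"]
    missing = [g for g in intake.index if g not in wide.index]
    if missing:
        raise DataError(f"no animal-food composition for groups {missing}")
    return wide.mul(intake, axis=0).sum(axis=0) * population


def compute_form_supply(
    data: FoodSystemDataset,
    config: ScenarioConfig,
    year: int,
    region: str = "national",
    diagnostics: list | None = None,
) -> pd.Series:
    """Edible grams/day per consumable form for one region-year.

    Applies the supply-chain balance per production identifier, the
    vegetable disaggregation, and the grain/oilseed processing splits.
    In provincial mode national trade and non-food-use quantities are
    allocated by the province's production share.
    """
    production = data.production_for(year, region)
    trade = data.trade_for(year)
    use = data.use_for(year)
    if region != "national":
        share = data.production_share(year, region)
        trade = trade.mul(share, axis=0).fillna(0.0)
        use = use.mul(share, axis=0).fillna(0.0)

    supply: dict[str, float] = {}
    pre_alpha: dict[str, float] = {}
    for crop in PRODUCTION_IDS:
        if crop not in production.index:
            raise DataError(f"no production row for crop {crop!r} in {year}/{region}")
        p = float(production[crop])
        f = float(
            trade.loc[crop, "imports"] - trade.loc[crop, "exports"] - trade.loc[crop, "stock_change"]
        ) if crop in trade.index else 0.0
        beta = float(use.loc[crop, ["feed", "seed", "other"]].sum()) if crop in use.index else 0.0
        label = f"{crop}/{year}/{region}"
        if crop == VEGETABLES_TOTAL:
            shares = data.veg_shares.set_index("subgroup")["share"].to_dict()
            sub_losses = {s: data.loss_vector(s) for s in VEG_SUBGROUPS}
            sub_alpha = {s: data.edible_proportion(s) for s in VEG_SUBGROUPS}
            veg = supply_chain.vegetable_subgroup_supply(
                p, f, beta, data.loss_vector(VEGETABLES_TOTAL), shares, sub_losses, sub_alpha,
                diagnostics=diagnostics,
            )
            supply.update(veg.to_dict())
        elif crop in PROCESSABLE:
            pre_alpha[crop] = supply_chain.food_supply(
                p, f, beta, data.loss_vector(crop), 1.0, diagnostics=diagnostics, label=label
            )
        else:
            supply[crop] = supply_chain.food_supply(
                p, f, beta, data.loss_vector(crop), data.edible_proportion(crop),
                diagnostics=diagnostics, label=label,
            )
    forms = supply_chain.split_and_process(
        pre_alpha, _spec_with_edible(data), oilseeds_as_seed=config.oilseeds_as_seed
    )
    supply.update(forms)
    return pd.Series(supply, dtype=float)


def _spec_with_edible(data: FoodSystemDataset) -> supply_chain.ProcessingSpec:
    spec = data.processing
    if not spec.form_edible:
        spec = replace(
            spec,
            form_edible=data.edible.set_index("form")["edible_proportion"].to_dict(),
        )
    return spec


def run_pipeline(
    data: FoodSystemDataset,
    config: ScenarioConfig | str,
    years: Iterable[int] | None = None,
    feed_shares: Mapping[str, float] | None = None,
    return_networks: bool = False,
):
    """Coverage, diversity and band per nutrient x year x region.

    Returns a tidy DataFrame with columns (scenario, region, year, nutrient,
    reference, coverage, diversity, band); with ``return_networks=True``
    also a dict mapping ``(region, year)`` to the per-source nutrient-supply
    matrix and the requirement table backing the coverages.
    """
    if isinstance(config, str):
        config = ScenarioConfig.from_id(config)
    transformed = apply_scenario(data, config, feed_shares)
    years = list(years) if years is not None else [transformed.years[-1]]
    missing = [y for y in years if y not in transformed.years]
    if missing:
        raise DataError(f"requested years absent from inputs: {missing}")
    regions = transformed.regions if config.aggregation == "provincial" else ["national"]

    records = []
    networks = {}
    diagnostics: list = []
    for year in years:
        for region in regions:
            form_supply = compute_form_supply(transformed, config, year, region, diagnostics)
            nutrient_supply = supply_chain.crop_nutrient_supply(
                form_supply.to_dict(),
                transformed.composition_wide(),
                transformed.processing.retention,
            )
            population = transformed.population_for(year, region)
            if config.animal_foods != "none":
                animal = animal_nutrient_supply(
                    transformed.animal_intake, transformed.animal_composition, population
                )
                nutrient_supply.loc[ANIMAL_NODE] = animal.reindex(
                    nutrient_supply.columns, fill_value=0.0
                )
            structure = transformed.structure_for(year, region)
            mu = requirements.requirement_bundle(transformed.dri, structure, population)
            records.extend(
                _summarise(nutrient_supply, mu, config.id, region, year)
            )
            if return_networks:
                networks[(region, year)] = {"supply": nutrient_supply, "mu": mu}
    if diagnostics:
        logger.info("%d negative availability balances clamped to zero", len(diagnostics))
    results = pd.DataFrame.from_records(
        records,
        columns=["scenario", "region", "year", "nutrient", "reference", "coverage", "diversity", "band"],
    )
    if return_networks:
        return results, networks
    return results


def _summarise(nutrient_supply: pd.DataFrame, mu: pd.DataFrame, scenario, region, year):
    rows = []
    for nutrient in nutrient_supply.columns:
        supplies = nutrient_supply[nutrient]
        diversity = metrics.source_diversity(supplies.to_numpy())
        refs = references_for(nutrient)
        coverages = {}
        for ref in refs:
            try:
                mu_val = mu.at[nutrient, ref]
            except KeyError:
                mu_val = float("nan")
            if pd.isna(mu_val):
                raise DataError(f"no {ref} requirement for nutrient {nutrient!r}")
            coverages[ref] = metrics.coverage(
                metrics.edge_weights(supplies.to_numpy(), mu_val)
            )
        if refs == ["EAR", "RNI"]:
            band = metrics.classify_coverage(
                nc_ear=coverages["EAR"], nc_rni=coverages["RNI"], kind="EAR_RNI"
            )
        else:
            band = metrics.classify_coverage(nc=coverages[refs[0]], kind=refs[0])
        for ref in refs:
            rows.append(
                (scenario, region, year, nutrient, ref, coverages[ref], diversity, band)
            )
    return rows


def run_trend(
    data: FoodSystemDataset,
    years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-year plant-food-only coverage and diversity at the national level.

    Uses current losses, trade and uses (no scenario adjustment) but
    excludes the animal-source node, tracing what the plant-based food
    supply alone covered in each year.
    """
    years = list(years) if years is not None else data.years
    return run_pipeline(data, TREND_CONFIG, years=years)
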