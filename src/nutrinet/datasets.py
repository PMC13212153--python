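"""The in-memory container for one complete food-system dataset.

All tables are tidy pandas DataFrames with documented columns; quantities
carry the units used throughout the package (tonnes/yr for supply-side
masses, grams/day for consumable supply, nutrient units per gram of edible
portion for contents).  ``region`` is ``"national"`` for single-region
datasets or a province identifier otherwise; national aggregates are
derived by summation (production, population) or population-weighted
averaging (age/sex structure), never stored redundantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .supply_chain import N_STAGES, ProcessingSpec


@dataclass
class FoodSystemDataset:
    """Bundle of the input tables the pipeline consumes.

    Attributes
    ----------
    production : (crop, region, year, tonnes)
        Annual primary production per province (or ``national``).
    trade : (crop, year, imports, exports, stock_change)  [tonnes/yr, national]
    use : (crop, year, feed, seed, other)  [tonnes/yr, national non-food use]
    losses : (id, stage, fraction)
        Stage 1-7 loss/waste fractions per production identifier and per
        vegetable subgroup (subgroups use stages 4-7; the aggregate row
        provides stages 1-3), constant over the study years.
    edible : (form, edible_proportion)
    veg_shares : (subgroup, share)
        Consumption shares disaggregating the vegetable aggregate; sum to 1.
    composition : (form, nutrient, content)
        Content per gram of edible portion (group-level representative value).
    members : (group, member, nutrient, content)
        Individual food items behind each aggregated composition row, used
        by the Monte Carlo uncertainty assessment.
    population : (region, year, population)
    structure : (region, year, age_group, sex, proportion)
        Age x sex stratum shares; sum to 1 per region-year.
    dri : (nutrient, age_group, sex, reference, value)
        Per-capita reference intakes (EAR/RNI/AI/EER) per stratum.
    animal_intake : (food_group, grams_per_capita_day)
    animal_composition : (food_group, nutrient, content)
    processing : ProcessingSpec
    """

    production: pd.DataFrame
    trade: pd.DataFrame
    use: pd.DataFrame
    losses: pd.DataFrame
    edible: pd.DataFrame
    veg_shares: pd.DataFrame
    composition: pd.DataFrame
    members: pd.DataFrame
    population: pd.DataFrame
    structure: pd.DataFrame
    dri: pd.DataFrame
    animal_intake: pd.DataFrame
    animal_composition: pd.DataFrame
    processing: ProcessingSpec = field(default_factory=ProcessingSpec)

    # -- convenience accessors -------------------------------------------

    @property
    def regions(self) -> list[str]:
        return sorted(self.production["region"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.production["year"].unique())

    def copy(self) -> "FoodSystemDataset":
        return replace(
            self,
            **{
                name: getattr(self, name).copy()
                for name in (
                    "production",
                    "trade",
                    "use",
                    "losses",
                    "edible",
                    "veg_shares",
                    "composition",
                    "members",
                    "population",
                    "structure",
                    "dri",
                    "animal_intake",
                    "animal_composition",
                )
            },
            processing=ProcessingSpec(
                wholegrain_fraction=dict(self.processing.wholegrain_fraction),
                food_oil_fraction=dict(self.processing.food_oil_fraction),
                extraction_rate=dict(self.processing.extraction_rate),
                shelling_rate=dict(self.processing.shelling_rate),
                form_edible=dict(self.processing.form_edible),
                retention=None
                if self.processing.retention is None
                else dict(self.processing.retention),
            ),
        )

    def production_for(self, year: int, region: str | None = None) -> pd.Series:
        """Tonnes per crop in *year*: one province, or the national sum."""
        rows = self.production[self.production["year"] == year]
        if rows.empty:
            raise DataError(f"no production data for year {year}")
        if region is not None and region != "national":
            rows = rows[rows["region"] == region]
            if rows.empty:
                raise DataError(f"no production data for region {region!r} in {year}")
        return rows.groupby("crop")["tonnes"].sum()

    def production_share(self, year: int, region: str) -> pd.Series:
        """Province share of national production, per crop (0 where national is 0)."""
        national = self.production_for(year)
        provincial = self.production_for(year, region)
        share = provincial.reindex(national.index, fill_value=0.0) / national.replace(0.0, np.nan)
        return share.fillna(0.0)

    def loss_vector(self, identifier: str) -> np.ndarray:
        rows = self.losses[self.losses["id"] == identifier].sort_values("stage")
        if len(rows) != N_STAGES:
            raise DataError(
                f"expected {N_STAGES} loss-stage rows for {identifier!r}, found {len(rows)}"
            )
        return rows["fraction"].to_numpy(dtype=float)

    def edible_proportion(self, form: str) -> float:
        rows = self.edible[self.edible["form"] == form]
        if rows.empty:
            raise DataError(f"no edible proportion for form {form!r}")
        return float(rows["edible_proportion"].iloc[0])

    def trade_for(self, year: int) -> pd.DataFrame:
        rows = self.trade[self.trade["year"] == year]
        if rows.empty:
            raise DataError(f"no trade data for year {year}")
        return rows.set_index("crop")

    def use_for(self, year: int) -> pd.DataFrame:
        rows = self.use[self.use["year"] == year]
        if rows.empty:
            raise DataError(f"no crop-use data for year {year}")
        return rows.set_index("crop")

    def population_for(self, year: int, region: str | None = None) -> float:
        rows = self.population[self.population["year"] == year]
        if rows.empty:
            raise DataError(f"no population data for year {year}")
        if region is not None and region != "national":
            rows = rows[rows["region"] == region]
            if rows.empty:
                raise DataError(f"no population for region {region!r} in {year}")
        return float(rows["population"].sum())

    def structure_for(self, year: int, region: str | None = None) -> pd.DataFrame:
        """Age x sex proportions for a region-year; national is population-weighted."""
        rows = self.structure[self.structure["year"] == year]
        if rows.empty:
            raise DataError(f"no population structure for year {year}")
        if region is not None and region != "national":
            rows = rows[rows["region"] == region]
            if rows.empty:
                raise DataError(f"no population structure for region {region!r} in {year}")
            return rows[["age_group", "sex", "proportion"]].reset_index(drop=True)
        pop = self.population[self.population["year"] == year].set_index("region")["population"]
        weighted = rows.assign(weight=rows["region"].map(pop))
        if weighted["weight"].isna().any():
            raise DataError("population structure references regions absent from population table")
        total = pop.loc[pop.index.isin(rows["region"].unique())].sum()
        out = (
            weighted.assign(part=weighted["proportion"] * weighted["weight"] / total)
            .groupby(["age_group", "sex"], as_index=False)["part"]
            .sum()
            .rename(columns={"part": "proportion"})
        )
        return out

    def composition_wide(self) -> pd.DataFrame:
        return self.composition.pivot(index="form", columns="nutrient", values="content")
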