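"""Synthetic food-system datasets with known ground truth.

The generator emulates the schemas and statistical structure of the data
sources the pipeline is built for — food-balance-sheet style supply tables
(production, trade, non-food use per crop and year), stage-wise loss
fractions, food-composition tables with member-level within-group variation,
age/sex population structures and dietary-reference-intake tables — without
claiming statistical realism for any particular country's agriculture.
Magnitudes are plausible-range (per-capita production and requirement values
of the right order), so that coverages land near one and both band
boundaries are exercised.

Alongside the tables, :func:`generate_with_ground_truth` records the
coverage and diversity implied by the generated inputs via the independent
loop oracle (:mod:`nutrinet.oracle`), giving tests an end-to-end recovery
surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oracle
from .datasets import FoodSystemDataset
from .errors import ConfigurationError
from .foods import (
    ANIMAL_GROUPS,
    BEANS,
    CEREALS,
    DUAL_USE_OIL,
    FRUITS,
    GRAIN_FORMS,
    NUTRIENTS,
    OIL_CROPS,
    OIL_FORMS,
    OIL_ONLY,
    PRODUCTION_IDS,
    SOURCES,
    TUBERS,
    VEG_SUBGROUPS,
    VEGETABLES_TOTAL,
)
from .supply_chain import ProcessingSpec

#: Nominal population used to scale production magnitudes (persons).
NOMINAL_POPULATION = 1.4e9

#: Plausible-range per-capita production, kg/person/yr.
BASE_PRODUCTION_KG_PER_CAPITA = {
    "rice": 140.0,
    "wheat": 95.0,
    "maize": 120.0,
    "sorghum": 3.0,
    "millet": 2.0,
    "other_cereals": 4.0,
    "potato": 70.0,
    "sweet_potato": 35.0,
    "soybean": 12.0,
    "other_beans": 3.0,
    "apple": 28.0,
    "pear": 12.0,
    "banana": 8.0,
    "citrus": 25.0,
    "grape": 9.0,
    "watermelon": 45.0,
    "casaba": 10.0,
    "other_fruits": 15.0,
    "vegetables": 480.0,
    "groundnut": 12.0,
    "rapeseed": 9.0,
    "sunflower_seed": 2.0,
    "sesame_seed": 0.5,
    "linseed": 0.3,
}

#: Content per gram of edible portion by food class (nutrient units as in
#: :data:`nutrinet.foods.NUTRIENTS`).
BASE_CONTENT = {
    #                cereal   tuber    bean    fruit     veg   oilseed     oil
    "energy":        (3.40,   0.90,    3.90,   0.50,    0.25,    5.50,    8.80),
    "protein":       (0.090,  0.020,   0.350,  0.005,   0.020,   0.220,   0.0),
    "carbohydrates": (0.740,  0.200,   0.250,  0.120,   0.040,   0.180,   0.0),
    "dietary_fibre": (0.030,  0.010,   0.100,  0.020,   0.015,   0.080,   0.0),
    "calcium":       (0.10,   0.10,    1.90,   0.08,    0.60,    0.60,    0.0),
    "potassium":     (1.30,   3.40,    15.0,   1.50,    2.20,    6.00,    0.0),
    "magnesium":     (0.90,   0.20,    2.20,   0.10,    0.18,    2.50,    0.0),
    "phosphorus":    (2.30,   0.40,    4.60,   0.15,    0.40,    3.50,    0.0),
    "iron":          (0.020,  0.006,   0.080,  0.004,   0.015,   0.050,   0.0),
    "zinc":          (0.015,  0.003,   0.030,  0.001,   0.004,   0.030,   0.0),
    "copper":        (0.0030, 0.0010,  0.0100, 0.0010,  0.0010,  0.0100,  0.0),
    "selenium":      (0.060,  0.008,   0.060,  0.002,   0.010,   0.050,   0.0),
    "vitamin_a":     (0.001,  0.020,   0.010,  0.050,   1.000,   0.010,   0.0),
    "vitamin_c":     (0.001,  0.200,   0.010,  0.300,   0.300,   0.0,     0.0),
    "vitamin_e":     (0.010,  0.003,   0.080,  0.010,   0.008,   0.150,   0.600),
    "thiamin":       (0.0030, 0.0010,  0.0040, 0.0003,  0.0005,  0.0070,  0.0),
    "riboflavin":    (0.0010, 0.0003,  0.0020, 0.0003,  0.0010,  0.0020,  0.0),
    "niacin":        (0.020,  0.010,   0.020,  0.003,   0.006,   0.100,   0.0),
}
_CLASS_INDEX = {"cereal": 0, "tuber": 1, "bean": 2, "fruit": 3, "vegetable": 4, "oilseed": 5, "oil": 6}

#: Per-capita adult reference intakes (EAR scale) in nutrient units/day.
BASE_REQUIREMENT = {
    "energy": 2100.0,
    "protein": 60.0,
    "carbohydrates": 120.0,
    "dietary_fibre": 22.0,
    "calcium": 800.0,
    "potassium": 2000.0,
    "magnesium": 330.0,
    "phosphorus": 700.0,
    "iron": 12.0,
    "zinc": 10.0,
    "copper": 0.8,
    "selenium": 50.0,
    "vitamin_a": 550.0,
    "vitamin_c": 85.0,
    "vitamin_e": 12.0,
    "thiamin": 1.2,
    "riboflavin": 1.2,
    "niacin": 13.0,
}

AGE_GROUPS = ["0-9", "10-17", "18-49", "50-64", "65plus"]
AGE_FACTORS = {"0-9": 0.6, "10-17": 1.1, "18-49": 1.0, "50-64": 0.95, "65plus": 0.9}
AGE_SHARE = {"0-9": 0.11, "10-17": 0.10, "18-49": 0.46, "50-64": 0.20, "65plus": 0.13}
SEX_FACTORS = {"m": 1.08, "f": 0.94}

#: Per-capita intakes of animal-based food groups, g/day.
ANIMAL_INTAKE_G_DAY = {"dairy": 30.0, "red_meat": 70.0, "poultry": 30.0, "eggs": 30.0, "aquatic": 40.0}

#: Content per gram for the animal-based food groups.
ANIMAL_CONTENT = {
    #                dairy  red_meat poultry  eggs  aquatic
    "energy":        (0.65,  2.00,   1.60,   1.45,   1.10),
    "protein":       (0.033, 0.200,  0.190,  0.130,  0.180),
    "carbohydrates": (0.050, 0.002,  0.001,  0.015,  0.002),
    "dietary_fibre": (0.0,   0.0,    0.0,    0.0,    0.0),
    "calcium":       (1.10,  0.06,   0.10,   0.55,   0.80),
    "potassium":     (1.40,  3.20,   2.50,   1.30,   3.00),
    "magnesium":     (0.11,  0.22,   0.22,   0.12,   0.30),
    "phosphorus":    (0.90,  2.00,   1.70,   1.80,   2.00),
    "iron":          (0.0005, 0.025, 0.012,  0.018,  0.010),
    "zinc":          (0.004, 0.045,  0.012,  0.012,  0.015),
    "copper":        (0.0001, 0.001, 0.0008, 0.0008, 0.0010),
    "selenium":      (0.020, 0.110,  0.110,  0.140,  0.300),
    "vitamin_a":     (0.24,  0.10,   0.40,   1.90,   0.20),
    "vitamin_c":     (0.010, 0.0,    0.0,    0.0,    0.0),
    "vitamin_e":     (0.002, 0.004,  0.010,  0.018,  0.012),
    "thiamin":       (0.0004, 0.003, 0.0008, 0.0011, 0.0007),
    "riboflavin":    (0.0014, 0.0018, 0.0011, 0.0027, 0.0010),
    "niacin":        (0.001, 0.045,  0.080,  0.002,  0.025),
}

# content multipliers for the whole-grain vs refined streams
_MACROS = {"energy", "protein", "carbohydrates"}


def _food_class(form: str) -> str:
    if form in CEREALS or any(form in pair for pair in GRAIN_FORMS.values()):
        return "cereal"
    if form in TUBERS:
        return "tuber"
    if form in BEANS:
        return "bean"
    if form in FRUITS:
        return "fruit"
    if form in VEG_SUBGROUPS:
        return "vegetable"
    if form in OIL_CROPS:
        return "oilseed"
    if form in OIL_FORMS:
        return "oil"
    raise KeyError(form)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic-data generator.

    ``n_years`` years starting at ``start_year`` (default 22, 1997-2018),
    ``n_provinces`` provinces (default 31; 1 means a single national
    region), the fixed 30-source crop list in six groups, 18 nutrient
    entries (energy + 17 nutrients) and a within-group coefficient of
    variation for member-level nutrient contents.  ``force_negative_bracket``
    inflates one crop's non-food use so the clamping path of the supply
    balance is exercised.
    """

    seed: int = 0
    n_years: int = 22
    start_year: int = 1997
    n_provinces: int = 31
    nutrients: tuple[str, ...] = tuple(NUTRIENTS)
    within_group_cv: float = 0.2
    members_per_group: int = 4
    force_negative_bracket: bool = False

    def __post_init__(self):
        if self.n_years < 1 or self.n_provinces < 1 or self.members_per_group < 1:
            raise ConfigurationError("counts must be at least 1")
        if self.within_group_cv < 0:
            raise ConfigurationError("within_group_cv must be non-negative")
        unknown = set(self.nutrients) - set(NUTRIENTS)
        if unknown:
            raise ConfigurationError(f"unknown nutrients {sorted(unknown)}")

    @property
    def n_nutrients(self) -> int:
        return len(self.nutrients)

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def provinces(self) -> list[str]:
        if self.n_provinces == 1:
            return ["national"]
        return [f"province_{i:02d}" for i in range(1, self.n_provinces + 1)]

    @property
    def crop_list(self) -> list[str]:
        return list(SOURCES)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_supply_tables(config: SyntheticConfig) -> dict:
    """Production, trade, non-food use, losses, edible proportions, shares.

    Provincial productions are drawn per crop (fixed province shares, a mild
    crop-specific trend and lognormal year noise); the national series is
    their sum.  Non-food uses are drawn as fractions of the loss-adjusted
    availability so the food balance stays positive by construction, unless
    ``force_negative_bracket`` is set.
    """
    rng = _rng(config, 1)
    years = config.years
    provinces = config.provinces

    prod_rows = []
    national_production: dict[tuple[str, int], float] = {}
    for crop in PRODUCTION_IDS:
        base = BASE_PRODUCTION_KG_PER_CAPITA[crop] * NOMINAL_POPULATION / 1000.0
        growth = rng.uniform(-0.01, 0.03)
        shares = rng.dirichlet(np.full(config.n_provinces, 2.0))
        noise = np.exp(rng.normal(0.0, 0.05, size=len(years)))
        for t, year in enumerate(years):
            national = base * (1.0 + growth) ** t * noise[t]
            values = national * shares
            national_production[(crop, year)] = float(values.sum())
            for prov, value in zip(provinces, values):
                prod_rows.append((crop, prov, year, float(value)))
    production = pd.DataFrame(prod_rows, columns=["crop", "region", "year", "tonnes"])

    loss_rows = []
    stage_ranges = [(0.03, 0.12), (0.02, 0.08), (0.02, 0.10), (0.02, 0.10), (0.02, 0.08), (0.02, 0.08), (0.04, 0.15)]
    perishable = set(FRUITS) | set(VEG_SUBGROUPS) | {VEGETABLES_TOTAL} | set(TUBERS)
    loss_lookup: dict[str, np.ndarray] = {}
    for identifier in PRODUCTION_IDS + VEG_SUBGROUPS:
        fractions = np.array([rng.uniform(lo, hi) for lo, hi in stage_ranges])
        if identifier in perishable:
            fractions = np.minimum(fractions * 1.5, 0.5)
        loss_lookup[identifier] = fractions
        for stage, fraction in enumerate(fractions, start=1):
            loss_rows.append((identifier, stage, float(fraction)))
    losses = pd.DataFrame(loss_rows, columns=["id", "stage", "fraction"])

    import_ratio = {crop: rng.uniform(0.02, 0.15) for crop in PRODUCTION_IDS}
    import_ratio["soybean"] = 1.5  # heavy import dependence of the feed bean
    trade_rows = []
    net_inflow: dict[tuple[str, int], float] = {}
    for crop in PRODUCTION_IDS:
        export_ratio = rng.uniform(0.0, 0.05)
        stock_ratio = rng.uniform(-0.03, 0.03)
        for year in years:
            p = national_production[(crop, year)]
            imports = import_ratio[crop] * p
            exports = export_ratio * p
            stock = stock_ratio * p
            trade_rows.append((crop, year, imports, exports, stock))
            net_inflow[(crop, year)] = imports - exports - stock
    trade = pd.DataFrame(trade_rows, columns=["crop", "year", "imports", "exports", "stock_change"])

    feed_frac = {"maize": 0.55, "soybean": 0.45, "vegetables": 0.04}
    use_rows = []
    for crop in PRODUCTION_IDS:
        ff = feed_frac.get(crop, rng.uniform(0.0, 0.04))
        sf = 0.03 if crop in CEREALS + BEANS + OIL_CROPS else 0.0
        of = 0.05 if crop == "maize" else rng.uniform(0.0, 0.03)
        pre = float(np.prod(1.0 - loss_lookup[crop][:3]))
        for year in years:
            available = national_production[(crop, year)] * pre + net_inflow[(crop, year)]
            feed = ff * available
            seed = sf * available
            other = of * available
            if config.force_negative_bracket and crop == "sorghum":
                other = 1.5 * available
            use_rows.append((crop, year, feed, seed, other))
    use = pd.DataFrame(use_rows, columns=["crop", "year", "feed", "seed", "other"])

    shares = np.array([0.15, 0.08, 0.20, 0.10, 0.35, 0.05, 0.07])
    shares = shares * np.exp(rng.normal(0.0, 0.1, size=7))
    shares = shares / shares.sum()
    veg_shares = pd.DataFrame({"subgroup": VEG_SUBGROUPS, "share": shares})

    alpha_range = {
        "cereal": (0.65, 0.80),
        "tuber": (0.85, 0.95),
        "bean": (0.95, 1.00),
        "fruit": (0.60, 0.90),
        "vegetable": (0.70, 0.95),
        "oilseed": (0.90, 1.00),
        "oil": (1.00, 1.00),
    }
    edible_rows = []
    grain_alpha = {grain: rng.uniform(0.68, 0.75) for grain in GRAIN_FORMS}
    for form in sorted(set(SOURCES) | set(sum(map(list, GRAIN_FORMS.values()), [])) | set(OIL_FORMS)):
        cls = _food_class(form)
        grain = next((g for g, pair in GRAIN_FORMS.items() if form in pair), None)
        if grain is not None:
            alpha = grain_alpha[grain]  # whole and refined streams share one milling yield
        elif form == "groundnut":
            alpha = 0.70  # kernel fraction of in-shell produce
        else:
            lo, hi = alpha_range[cls]
            alpha = rng.uniform(lo, hi) if hi > lo else 1.0
        edible_rows.append((form, float(alpha)))
    edible = pd.DataFrame(edible_rows, columns=["form", "edible_proportion"])

    processing = ProcessingSpec(
        wholegrain_fraction={"rice": 0.05, "wheat": 0.05},
        food_oil_fraction={"soybean": 0.30, "groundnut": 0.45, "sesame_seed": 0.30},
        extraction_rate={
            "soybean": 0.16,
            "groundnut": 0.40,
            "sesame_seed": 0.45,
            "sunflower_seed": 0.40,
            "linseed": 0.33,
            "rapeseed": 0.38,
        },
        shelling_rate={"groundnut": 0.7},
        form_edible=dict(edible_rows),
    )

    return {
        "production": production,
        "trade": trade,
        "use": use,
        "losses": losses,
        "edible": edible,
        "veg_shares": veg_shares,
        "processing": processing,
    }


def generate_composition_tables(config: SyntheticConfig) -> dict:
    """Group-level contents per form plus member-level draws per group.

    Member contents are drawn log-normally around the group value with the
    configured coefficient of variation (mean-preserving, non-negative by
    construction); a zero CV collapses every member onto its group value.
    Whole-grain streams carry higher micronutrient contents than the
    refined streams of the same grain.
    """
    rng = _rng(config, 2)
    nutrients = list(config.nutrients)

    contents: dict[str, dict[str, float]] = {}
    for crop in SOURCES:
        cls = _food_class(crop)
        contents[crop] = {
            j: BASE_CONTENT[j][_CLASS_INDEX[cls]] * float(np.exp(rng.normal(0.0, 0.4)))
            for j in nutrients
        }
    for grain, (whole, refined) in GRAIN_FORMS.items():
        base = contents[grain]
        contents[whole] = {
            j: base[j] * (rng.uniform(1.00, 1.05) if j in _MACROS else rng.uniform(1.2, 1.8))
            for j in nutrients
        }
        contents[refined] = {
            j: base[j] * (rng.uniform(0.95, 1.00) if j in _MACROS else rng.uniform(0.6, 0.9))
            for j in nutrients
        }
    for seed, oil in {**DUAL_USE_OIL, **OIL_ONLY}.items():
        contents[oil] = {
            j: BASE_CONTENT[j][_CLASS_INDEX["oil"]] * float(np.exp(rng.normal(0.0, 0.3)))
            for j in nutrients
        }

    comp_rows = [
        (form, j, value)
        for form, per_nutrient in sorted(contents.items())
        for j, value in per_nutrient.items()
    ]
    composition = pd.DataFrame(comp_rows, columns=["form", "nutrient", "content"])

    cv = config.within_group_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    member_rows = []
    for form in sorted(contents):
        for m in range(1, config.members_per_group + 1):
            draws = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=len(nutrients))) if sigma > 0 else np.ones(len(nutrients))
            for j, d in zip(nutrients, draws):
                member_rows.append((form, f"{form}_member_{m:02d}", j, contents[form][j] * float(d)))
    members = pd.DataFrame(member_rows, columns=["group", "member", "nutrient", "content"])

    animal_rows = [
        (group, j, ANIMAL_CONTENT[j][k] * float(np.exp(rng.normal(0.0, 0.1))))
        for k, group in enumerate(ANIMAL_GROUPS)
        for j in nutrients
    ]
    animal_composition = pd.DataFrame(animal_rows, columns=["food_group", "nutrient", "content"])
    animal_intake = pd.DataFrame(
        {
            "food_group": ANIMAL_GROUPS,
            "grams_per_capita_day": [ANIMAL_INTAKE_G_DAY[g] for g in ANIMAL_GROUPS],
        }
    )

    return {
        "composition": composition,
        "members": members,
        "animal_composition": animal_composition,
        "animal_intake": animal_intake,
    }


def generate_population_and_dri(config: SyntheticConfig) -> dict:
    """Population totals, age/sex structure and reference-intake tables.

    Stratum proportions sum to one per region-year; EAR <= RNI holds per
    stratum by construction.  Potassium carries an adequate intake only and
    energy an estimated energy requirement, mirroring the reference types
    the requirement aggregation supports.
    """
    rng = _rng(config, 3)
    years = config.years
    provinces = config.provinces

    base_shares = rng.dirichlet(np.full(config.n_provinces, 5.0))
    pop_rows = []
    for t, year in enumerate(years):
        national = NOMINAL_POPULATION * (1.005) ** t
        for prov, share in zip(provinces, base_shares):
            pop_rows.append((prov, year, national * share))
    population = pd.DataFrame(pop_rows, columns=["region", "year", "population"])

    struct_rows = []
    for prov in provinces:
        template = np.array(
            [AGE_SHARE[k] * 0.5 * np.exp(rng.normal(0.0, 0.1)) for k in AGE_GROUPS for _ in ("m", "f")]
        )
        template = template / template.sum()
        strata = [(k, s) for k in AGE_GROUPS for s in ("m", "f")]
        for year in years:
            for (age, sex), share in zip(strata, template):
                struct_rows.append((prov, year, age, sex, float(share)))
    structure = pd.DataFrame(struct_rows, columns=["region", "year", "age_group", "sex", "proportion"])

    dri_rows = []
    for nutrient in config.nutrients:
        base = BASE_REQUIREMENT[nutrient]
        for age in AGE_GROUPS:
            for sex in ("m", "f"):
                value = base * AGE_FACTORS[age] * SEX_FACTORS[sex] * float(np.exp(rng.normal(0.0, 0.05)))
                if nutrient == "potassium":
                    dri_rows.append((nutrient, age, sex, "AI", value))
                elif nutrient == "energy":
                    dri_rows.append((nutrient, age, sex, "EER", value))
                else:
                    dri_rows.append((nutrient, age, sex, "EAR", value))
                    dri_rows.append((nutrient, age, sex, "RNI", value * rng.uniform(1.15, 1.35)))
    dri = pd.DataFrame(dri_rows, columns=["nutrient", "age_group", "sex", "reference", "value"])

    return {"population": population, "structure": structure, "dri": dri}


def generate_dataset(config: SyntheticConfig) -> FoodSystemDataset:
    """Assemble a complete, internally consistent synthetic dataset."""
    supply = generate_supply_tables(config)
    comp = generate_composition_tables(config)
    popdri = generate_population_and_dri(config)
    return FoodSystemDataset(
        production=supply["production"],
        trade=supply["trade"],
        use=supply["use"],
        losses=supply["losses"],
        edible=supply["edible"],
        veg_shares=supply["veg_shares"],
        composition=comp["composition"],
        members=comp["members"],
        population=popdri["population"],
        structure=popdri["structure"],
        dri=popdri["dri"],
        animal_intake=comp["animal_intake"],
        animal_composition=comp["animal_composition"],
        processing=supply["processing"],
    )


def generate_with_ground_truth(config: SyntheticConfig):
    """Dataset plus independently re-derived per-year coverage/diversity.

    The ground truth is computed at generation time by the loop oracle,
    for the baseline network with the animal node (scenario S1 semantics on
    current settings) and for the plant-food-only network, at the national
    level for every year.
    """
    data = generate_dataset(config)
    records = []
    for year in config.years:
        for label, include_animal in (("S1", True), ("PFS", False)):
            for rec in oracle.ground_truth_metrics(data, year, "national", include_animal):
                records.append({"scenario": label, "region": "national", "year": year, **rec})
    truth = pd.DataFrame.from_records(records)
    return data, truth
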