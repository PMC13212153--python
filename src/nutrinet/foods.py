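"""Canonical food-system vocabulary: crops, groups, processed forms, nutrients.

The model tracks 30 plant-based sources in six crop groups. Production
statistics report vegetables only as a single aggregate, so the production
axis has 24 identifiers (23 individual crops plus ``vegetables``) while the
source axis of the crop-nutrient network has 30 (the 23 crops plus 7
vegetable subgroups obtained by disaggregating the aggregate with
consumption shares).
"""

from __future__ import annotations

CEREALS = ["rice", "wheat", "maize", "sorghum", "millet", "other_cereals"]
TUBERS = ["potato", "sweet_potato"]
BEANS = ["soybean", "other_beans"]
FRUITS = [
    "apple",
    "pear",
    "banana",
    "citrus",
    "grape",
    "watermelon",
    "casaba",
    "other_fruits",
]
OIL_CROPS = ["groundnut", "rapeseed", "sunflower_seed", "sesame_seed", "linseed"]

VEGETABLES_TOTAL = "vegetables"
VEG_SUBGROUPS = [
    "root_vegetables",
    "leguminous_vegetables",
    "cucurbit_solanaceous_vegetables",
    "allium_vegetables",
    "stem_leafy_flower_vegetables",
    "aquatic_vegetables",
    "mushrooms",
]

#: Crop group membership (six groups).
CROP_GROUPS = {
    "cereals": CEREALS,
    "tubers": TUBERS,
    "beans": BEANS,
    "fruits": FRUITS,
    "vegetables": VEG_SUBGROUPS,
    "oil_crops": OIL_CROPS,
}

#: Identifiers carried by production / trade / use statistics (24).
PRODUCTION_IDS = CEREALS + TUBERS + BEANS + FRUITS + [VEGETABLES_TOTAL] + OIL_CROPS

#: Source nodes of the crop-nutrient network (30).
SOURCES = CEREALS + TUBERS + BEANS + FRUITS + VEG_SUBGROUPS + OIL_CROPS

#: Aggregated animal-based foods enter as one extra node in S1/S2.
ANIMAL_NODE = "animal_foods"

ANIMAL_GROUPS = ["dairy", "red_meat", "poultry", "eggs", "aquatic"]

# --- processed forms ------------------------------------------------------

#: Grains split into a whole-grain and a refined stream.
GRAIN_FORMS = {
    "rice": ("brown_rice", "refined_rice"),
    "wheat": ("whole_wheat_flour", "refined_wheat_flour"),
}

#: Oilseeds consumed partly as seed, partly processed to vegetable oil.
DUAL_USE_OIL = {
    "soybean": "soybean_oil",
    "groundnut": "groundnut_oil",
    "sesame_seed": "sesame_oil",
}

#: Oilseeds whose food supply is fully converted to vegetable oil.
OIL_ONLY = {
    "sunflower_seed": "sunflower_oil",
    "linseed": "linseed_oil",
    "rapeseed": "rapeseed_oil",
}

#: Production identifiers that pass through split_and_process.
PROCESSABLE = list(GRAIN_FORMS) + list(DUAL_USE_OIL) + list(OIL_ONLY)

OIL_FORMS = list(DUAL_USE_OIL.values()) + list(OIL_ONLY.values())


def _form_to_source() -> dict[str, str]:
    mapping = {s: s for s in SOURCES}
    for grain, (whole, refined) in GRAIN_FORMS.items():
        mapping[whole] = grain
        mapping[refined] = grain
    for seed, oil in {**DUAL_USE_OIL, **OIL_ONLY}.items():
        mapping[oil] = seed
    return mapping


#: Every consumable form mapped back to its source node.
FORM_TO_SOURCE = _form_to_source()

#: All consumable forms (composition-table rows).
ALL_FORMS = sorted(FORM_TO_SOURCE)

# --- nutrients ------------------------------------------------------------

#: Dietary energy plus 17 nutrients (units noted; contents are per gram of
#: edible portion).
NUTRIENTS = [
    "energy",  # kcal
    "protein",  # g
    "carbohydrates",  # g
    "dietary_fibre",  # g
    "calcium",  # mg
    "potassium",  # mg
    "magnesium",  # mg
    "phosphorus",  # mg
    "iron",  # mg
    "zinc",  # mg
    "copper",  # mg
    "selenium",  # ug
    "vitamin_a",  # ug RAE
    "vitamin_c",  # mg
    "vitamin_e",  # mg
    "thiamin",  # mg
    "riboflavin",  # mg
    "niacin",  # mg
]

#: Nutrients whose requirement is an adequate intake (no EAR/RNI).
AI_NUTRIENTS = {"potassium"}
#: Nutrients whose requirement is an estimated energy requirement.
EER_NUTRIENTS = {"energy"}


def references_for(nutrient: str) -> list[str]:
    """Reference-intake types applicable to *nutrient* (EAR/RNI, AI or EER)."""
    if nutrient in AI_NUTRIENTS:
        return ["AI"]
    if nutrient in EER_NUTRIENTS:
        return ["EER"]
    return ["EAR", "RNI"]


#: Annual tonnes to average daily grams.
TONNES_YEAR_TO_G_DAY = 1e6 / 365.0
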