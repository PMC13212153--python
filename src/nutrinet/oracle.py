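"""Literal, loop-based re-derivation of coverage and source diversity.

This module is a deliberately plain transcription of the model equations —
explicit Python loops over dictionaries, ``math`` arithmetic, sources
iterated in reverse order — kept free of the vectorised pipeline code in
:mod:`nutrinet.scenarios` and :mod:`nutrinet.metrics`.  The synthetic-data
generator records its ground truth through this path, giving the test
suite an independent oracle for end-to-end recovery checks.
"""

from __future__ import annotations

import math

from .datasets import FoodSystemDataset
from .foods import (
    ANIMAL_NODE,
    DUAL_USE_OIL,
    GRAIN_FORMS,
    OIL_ONLY,
    PRODUCTION_IDS,
    VEG_SUBGROUPS,
    VEGETABLES_TOTAL,
    references_for,
)


def entropy_exponential(weights) -> float:
    """exp(-sum e_i ln e_i) by direct looping; NaN when the total is zero."""
    total = 0.0
    for w in weights:
        total += w
    if total == 0.0:
        return float("nan")
    entropy = 0.0
    for w in reversed(list(weights)):
        share = w / total
        if share > 0.0:
            entropy -= share * math.log(share)
    return math.exp(entropy)


def _losses(data: FoodSystemDataset, identifier: str) -> list[float]:
    rows = data.losses[data.losses["id"] == identifier].sort_values("stage")
    return [float(x) for x in rows["fraction"]]


def _alpha(data: FoodSystemDataset, form: str) -> float:
    rows = data.edible[data.edible["form"] == form]
    return float(rows["edible_proportion"].iloc[0])


def _bracket(p, f, beta, losses):
    kept = 1.0
    for h in (0, 1, 2):
        kept *= 1.0 - losses[h]
    value = p * kept + f - beta
    return value if value > 0.0 else 0.0


def _consumer_stages(losses):
    kept = 1.0
    for h in (3, 4, 5, 6):
        kept *= 1.0 - losses[h]
    return kept


def form_supplies(
    data: FoodSystemDataset,
    year: int,
    region: str = "national",
    oilseeds_as_seed: bool = False,
) -> dict[str, float]:
    """Edible grams/day per consumable form, computed with explicit loops."""
    conv = 1e6 / 365.0
    production = {}
    for row in data.production.itertuples():
        if row.year != year:
            continue
        if region != "national" and row.region != region:
            continue
        production[row.crop] = production.get(row.crop, 0.0) + float(row.tonnes)
    national = {}
    if region != "national":
        for row in data.production.itertuples():
            if row.year == year:
                national[row.crop] = national.get(row.crop, 0.0) + float(row.tonnes)

    trade = {}
    for row in data.trade.itertuples():
        if row.year == year:
            trade[row.crop] = float(row.imports) - float(row.exports) - float(row.stock_change)
    use = {}
    for row in data.use.itertuples():
        if row.year == year:
            use[row.crop] = float(row.feed) + float(row.seed) + float(row.other)

    shares = {row.subgroup: float(row.share) for row in data.veg_shares.itertuples()}
    spec = data.processing

    supplies: dict[str, float] = {}
    for crop in PRODUCTION_IDS:
        p = production.get(crop, 0.0)
        f = trade.get(crop, 0.0)
        beta = use.get(crop, 0.0)
        if region != "national":
            ref = national.get(crop, 0.0)
            scale = p / ref if ref > 0.0 else 0.0
            f *= scale
            beta *= scale
        losses = _losses(data, crop)
        if crop == VEGETABLES_TOTAL:
            bracket = _bracket(p, f, beta, losses)
            for sub in VEG_SUBGROUPS:
                sub_losses = _losses(data, sub)
                supplies[sub] = (
                    bracket
                    * shares[sub]
                    * _consumer_stages(sub_losses)
                    * conv
                    * _alpha(data, sub)
                )
            continue
        retail = _bracket(p, f, beta, losses) * _consumer_stages(losses) * conv
        if crop in GRAIN_FORMS:
            whole, refined = GRAIN_FORMS[crop]
            w = spec.wholegrain_fraction.get(crop, 0.0)
            supplies[whole] = retail * w * _alpha(data, whole)
            supplies[refined] = retail * (1.0 - w) * _alpha(data, refined)
        elif crop in DUAL_USE_OIL:
            oil = DUAL_USE_OIL[crop]
            phi = 1.0 if oilseeds_as_seed else spec.food_oil_fraction.get(crop, 1.0)
            supplies[crop] = retail * phi * _alpha(data, crop)
            supplies[oil] = (
                retail
                * (1.0 - phi)
                * spec.shelling_rate.get(crop, 1.0)
                * spec.extraction_rate[crop]
                * _alpha(data, oil)
            )
        elif crop in OIL_ONLY:
            oil = OIL_ONLY[crop]
            if oilseeds_as_seed:
                supplies[crop] = retail * _alpha(data, crop)
                supplies[oil] = 0.0
            else:
                supplies[crop] = 0.0
                supplies[oil] = (
                    retail
                    * spec.shelling_rate.get(crop, 1.0)
                    * spec.extraction_rate[crop]
                    * _alpha(data, oil)
                )
        else:
            supplies[crop] = retail * _alpha(data, crop)
    return supplies


def ground_truth_metrics(
    data: FoodSystemDataset,
    year: int,
    region: str = "national",
    include_animal: bool = True,
) -> list[dict]:
    """Coverage, diversity and band per nutrient for one region-year.

    Baseline (current-settings) accounting only; returns a list of plain
    records ``{nutrient, reference, coverage, diversity, band}``.
    """
    supplies = form_supplies(data, year, region)
    contents: dict[tuple[str, str], float] = {}
    nutrients: list[str] = []
    for row in data.composition.itertuples():
        contents[(row.form, row.nutrient)] = float(row.content)
        if row.nutrient not in nutrients:
            nutrients.append(row.nutrient)

    retention = data.processing.retention or {}

    # nutrient supply per source node, forms folded back onto sources
    per_source: dict[str, dict[str, float]] = {}
    for form, grams in supplies.items():
        if form in GRAIN_FORMS.get("rice", ()) or form in GRAIN_FORMS.get("wheat", ()):
            source = "rice" if form in GRAIN_FORMS["rice"] else "wheat"
        else:
            source = form
            for seed, oil in list(DUAL_USE_OIL.items()) + list(OIL_ONLY.items()):
                if form == oil:
                    source = seed
        bucket = per_source.setdefault(source, {})
        for j in nutrients:
            amount = grams * contents[(form, j)] * retention.get((form, j), 1.0)
            bucket[j] = bucket.get(j, 0.0) + amount

    population = 0.0
    for row in data.population.itertuples():
        if row.year != year:
            continue
        if region != "national" and row.region != region:
            continue
        population += float(row.population)

    if include_animal:
        intake = {
            row.food_group: float(row.grams_per_capita_day)
            for row in data.animal_intake.itertuples()
        }
        animal: dict[str, float] = {j: 0.0 for j in nutrients}
        for row in data.animal_composition.itertuples():
            if row.food_group in intake:
                animal[row.nutrient] += intake[row.food_group] * float(row.content)
        per_source[ANIMAL_NODE] = {j: animal[j] * population for j in nutrients}

    mu = _population_requirements(data, year, region, population, nutrients)

    records = []
    for j in nutrients:
        weights_by_source = [per_source[s].get(j, 0.0) for s in sorted(per_source)]
        diversity = entropy_exponential(weights_by_source)
        total_supply = 0.0
        for w in weights_by_source:
            total_supply += w
        refs = references_for(j)
        cov = {ref: total_supply / mu[(j, ref)] for ref in refs}
        if refs == ["EAR", "RNI"]:
            if cov["RNI"] >= 1.0:
                band = "high"
            elif cov["EAR"] >= 1.0:
                band = "medium"
            else:
                band = "low"
        else:
            c = cov[refs[0]]
            band = "high" if c > 1.0 else ("medium" if c >= 0.8 else "low")
        for ref in refs:
            records.append(
                {
                    "nutrient": j,
                    "reference": ref,
                    "coverage": cov[ref],
                    "diversity": diversity,
                    "band": band,
                }
            )
    return records


def _population_requirements(data, year, region, population, nutrients):
    pops = {}
    for row in data.population.itertuples():
        if row.year == year:
            pops[row.region] = float(row.population)
    weights: dict[tuple[str, str], float] = {}
    for row in data.structure.itertuples():
        if row.year != year:
            continue
        if region != "national":
            if row.region == region:
                weights[(row.age_group, row.sex)] = (
                    weights.get((row.age_group, row.sex), 0.0) + float(row.proportion)
                )
        else:
            weights[(row.age_group, row.sex)] = weights.get(
                (row.age_group, row.sex), 0.0
            ) + float(row.proportion) * pops[row.region] / sum(pops.values())

    values: dict[tuple[str, str, str, str], float] = {}
    for row in data.dri.itertuples():
        values[(row.nutrient, row.reference, row.age_group, row.sex)] = float(row.value)

    mu: dict[tuple[str, str], float] = {}
    for j in nutrients:
        for ref in references_for(j):
            acc = 0.0
            for (age, sex), r in weights.items():
                acc += values[(j, ref, age, sex)] * r
            mu[(j, ref)] = acc * population
    return mu
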