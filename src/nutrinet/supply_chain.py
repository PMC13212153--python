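"""Supply-chain accounting: from production statistics to food on the plate.

The quantity of a crop available for food consumption in a year is obtained
by following the mass through seven supply-chain stages::

    S = (p * (1-l1)(1-l2)(1-l3) + f - beta) * (1-l4)(1-l5)(1-l6)(1-l7)
        * 1e6/365 * alpha

where ``p`` is annual production (tonnes/yr), ``l1..l3`` are loss fractions
at the production, postharvest-handling and storage stages, ``f`` is the net
inflow (imports minus exports, corrected for stock changes), ``beta`` the
non-food use (feed, seed, other), ``l4..l7`` the loss/waste fractions at the
processing, distribution, retail and consumption stages, ``1e6/365``
converts tonnes per year to grams per day and ``alpha`` is the edible
proportion.  A negative bracket (net exports plus non-food use exceeding
loss-adjusted availability) is physically impossible as food supply and is
clamped to zero with a diagnostic.

Grains and oilseeds are additionally partitioned into processed forms
(whole/refined grain streams, seed-consumption and vegetable-oil streams)
before nutrient contents are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError
from .foods import (
    DUAL_USE_OIL,
    FORM_TO_SOURCE,
    GRAIN_FORMS,
    OIL_ONLY,
    TONNES_YEAR_TO_G_DAY,
    VEG_SUBGROUPS,
)

logger = logging.getLogger(__name__)

N_STAGES = 7
_PRE_STAGES = slice(0, 3)  # production, postharvest handling, storage
_POST_STAGES = slice(3, 7)  # processing, distribution, retail, consumption


@dataclass
class ProcessingSpec:
    """Processing conventions applied after the supply-chain accounting.

    Parameters
    ----------
    wholegrain_fraction
        Per grain (rice, wheat): fraction of the grain stream supplied as
        whole grain; the remainder is refined.
    food_oil_fraction
        Per dual-use oilseed (soybean, groundnut, sesame): fraction consumed
        directly as seed; the remainder is pressed to vegetable oil.
    extraction_rate
        Oil mass per unit (shelled) seed mass, per oilseed.
    shelling_rate
        Kernel fraction of in-shell produce, applied on the oil stream
        (groundnut 0.7; 1.0 where not applicable).
    form_edible
        Edible proportion per processed form; oils default to 1.
    retention
        Optional ``(form, nutrient) -> factor`` multiplicative retention
        factors in [0, 1] (cooking-loss hook); missing entries default to 1.
    """

    wholegrain_fraction: dict[str, float] = field(default_factory=dict)
    food_oil_fraction: dict[str, float] = field(default_factory=dict)
    extraction_rate: dict[str, float] = field(default_factory=dict)
    shelling_rate: dict[str, float] = field(default_factory=dict)
    form_edible: dict[str, float] = field(default_factory=dict)
    retention: dict[tuple[str, str], float] | None = None

    def __post_init__(self):
        for name in ("wholegrain_fraction", "food_oil_fraction", "extraction_rate", "shelling_rate", "form_edible"):
            for key, value in getattr(self, name).items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigurationError(f"{name}[{key}] = {value} outside [0, 1]")
        if self.retention is not None:
            for key, value in self.retention.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigurationError(f"retention[{key}] = {value} outside [0, 1]")

    def alpha(self, form: str) -> float:
        return self.form_edible.get(form, 1.0)


def _check_losses(losses: np.ndarray) -> np.ndarray:
    losses = np.asarray(losses, dtype=float)
    if losses.shape[-1] != N_STAGES:
        raise DomainError(f"expected {N_STAGES} stage loss fractions, got shape {losses.shape}")
    if np.any(losses < 0.0) or np.any(losses >= 1.0):
        raise DomainError("loss fractions must lie in [0, 1)")
    return losses


def food_supply(
    production: float,
    net_inflow: float,
    nonfood_use: float,
    loss_fractions,
    edible_proportion: float = 1.0,
    diagnostics: list | None = None,
    label: str = "",
) -> float:
    """Grams per day of a crop available for food consumption.

    Implements the seven-stage supply-chain balance described in the module
    docstring.  ``production``, ``net_inflow`` and ``nonfood_use`` are in
    tonnes per year.  A negative pre-processing balance is clamped to zero
    and appended to ``diagnostics`` when a list is supplied.
    """
    losses = _check_losses(loss_fractions)
    if not 0.0 < edible_proportion <= 1.0:
        raise DomainError(f"edible proportion must lie in (0, 1], got {edible_proportion}")
    if production < 0:
        raise DomainError("production must be non-negative")
    bracket = production * np.prod(1.0 - losses[_PRE_STAGES]) + net_inflow - nonfood_use
    if bracket < 0.0:
        record = {"label": label, "bracket_tonnes": float(bracket)}
        if diagnostics is not None:
            diagnostics.append(record)
        logger.warning("negative food-availability balance clamped to 0: %s", record)
        bracket = 0.0
    return float(
        bracket * np.prod(1.0 - losses[_POST_STAGES]) * TONNES_YEAR_TO_G_DAY * edible_proportion
    )


def vegetable_subgroup_supply(
    production: float,
    net_inflow: float,
    nonfood_use: float,
    total_losses,
    shares: Mapping[str, float],
    subgroup_losses: Mapping[str, np.ndarray],
    subgroup_alpha: Mapping[str, float],
    diagnostics: list | None = None,
) -> pd.Series:
    """Disaggregate the total vegetable supply into the seven subgroups.

    The production-side balance (stages 1-3, trade, non-food use) is taken
    on the vegetable aggregate; each subgroup then receives its consumption
    share ``theta`` and passes its own stage 4-7 losses and edible
    proportion.
    """
    share_values = np.array([shares[s] for s in VEG_SUBGROUPS], dtype=float)
    if abs(share_values.sum() - 1.0) > 1e-6:
        raise DataError(f"vegetable shares must sum to 1, got {share_values.sum():.6f}")
    total = _check_losses(total_losses)
    bracket = production * np.prod(1.0 - total[_PRE_STAGES]) + net_inflow - nonfood_use
    if bracket < 0.0:
        record = {"label": "vegetables", "bracket_tonnes": float(bracket)}
        if diagnostics is not None:
            diagnostics.append(record)
        logger.warning("negative vegetable balance clamped to 0: %s", record)
        bracket = 0.0
    out = {}
    for sub, theta in zip(VEG_SUBGROUPS, share_values):
        losses = _check_losses(subgroup_losses[sub])
        alpha = subgroup_alpha[sub]
        if not 0.0 < alpha <= 1.0:
            raise DomainError(f"edible proportion for {sub} must lie in (0, 1]")
        out[sub] = (
            bracket
            * theta
            * np.prod(1.0 - losses[_POST_STAGES])
            * TONNES_YEAR_TO_G_DAY
            * alpha
        )
    return pd.Series(out, dtype=float)


def split_and_process(
    supply: Mapping[str, float],
    spec: ProcessingSpec,
    oilseeds_as_seed: bool = False,
) -> dict[str, float]:
    """Partition grain and oilseed retail mass into processed-form supplies.

    ``supply`` maps a processable crop to its retail-level mass in g/day
    *before* the edible proportion is applied; the returned mapping carries
    edible grams per day per processed form.  Mass is never created: with
    edible proportions and extraction below one, output is below input.

    When ``oilseeds_as_seed`` is set (self-sufficiency scenarios) every
    oilseed stream is routed to direct seed consumption instead of oil.
    """
    out: dict[str, float] = {}
    for crop, mass in supply.items():
        if mass < 0:
            raise DomainError(f"negative supply for {crop}")
        if crop in GRAIN_FORMS:
            whole, refined = GRAIN_FORMS[crop]
            w = spec.wholegrain_fraction.get(crop, 0.0)
            out[whole] = mass * w * spec.alpha(whole)
            out[refined] = mass * (1.0 - w) * spec.alpha(refined)
        elif crop in DUAL_USE_OIL:
            oil = DUAL_USE_OIL[crop]
            phi = 1.0 if oilseeds_as_seed else spec.food_oil_fraction.get(crop, 1.0)
            out[crop] = mass * phi * spec.alpha(crop)
            out[oil] = (
                mass
                * (1.0 - phi)
                * spec.shelling_rate.get(crop, 1.0)
                * _extraction(spec, crop)
                * spec.alpha(oil)
            )
        elif crop in OIL_ONLY:
            oil = OIL_ONLY[crop]
            if oilseeds_as_seed:
                out[crop] = mass * spec.alpha(crop)
                out[oil] = 0.0
            else:
                out[crop] = 0.0
                out[oil] = (
                    mass
                    * spec.shelling_rate.get(crop, 1.0)
                    * _extraction(spec, crop)
                    * spec.alpha(oil)
                )
        else:
            raise ConfigurationError(f"unknown processed form for crop {crop!r}")
    return out


def _extraction(spec: ProcessingSpec, crop: str) -> float:
    try:
        return spec.extraction_rate[crop]
    except KeyError:
        raise ConfigurationError(f"no oil extraction rate configured for {crop!r}") from None


def crop_nutrient_supply(
    form_supply: Mapping[str, float],
    contents: pd.DataFrame,
    retention: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Nutrient supply per source node (units/day), summed over processed forms.

    Parameters
    ----------
    form_supply
        Edible grams per day per consumable form.
    contents
        Nutrient content per gram of edible portion, indexed by form with
        one column per nutrient (wide), or the tidy
        ``(form, nutrient, content)`` long format.
    retention
        Optional ``(form, nutrient) -> factor`` cooking-retention factors.

    Returns
    -------
    DataFrame indexed by source node, one column per nutrient.
    """
    if set(contents.columns) >= {"form", "nutrient", "content"}:
        contents = contents.pivot(index="form", columns="nutrient", values="content")
    rows = {}
    for form, grams in form_supply.items():
        if form not in contents.index:
            raise DataError(f"no nutrient-content row for form {form!r}")
        vec = contents.loc[form].astype(float)
        if retention:
            factors = pd.Series(
                {j: retention.get((form, j), 1.0) for j in vec.index}, dtype=float
            )
            vec = vec * factors
        source = FORM_TO_SOURCE.get(form, form)
        contribution = grams * vec
        rows[source] = rows[source] + contribution if source in rows else contribution
    result = pd.DataFrame(rows).T
    result.index.name = "source"
    result.columns.name = "nutrient"
    return result
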