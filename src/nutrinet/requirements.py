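"""Population-level nutrient requirements from dietary reference intakes.

The population requirement ``mu`` for a nutrient is the age- and sex-
weighted mean per-capita reference intake times the total population::

    mu = sum_k (v_km * r_km + v_kf * r_kf) * pop

with ``v`` the per-capita reference value (EAR, RNI, AI or EER) for age
group ``k`` and sex, and ``r`` the stratum's share of the population.
EAR-based requirements characterise what would satisfy half the
individuals in each stratum; RNI-based requirements (set above the EAR)
give greater certainty of sufficiency.  Potassium carries only an
adequate intake (AI) and dietary energy an estimated energy requirement
(EER) at a moderate physical-activity level.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigurationError, DataError
from .foods import NUTRIENTS, references_for

VALID_REFERENCES = ("EAR", "RNI", "AI", "EER")


def per_capita_requirement(
    dri: pd.DataFrame,
    structure: pd.DataFrame,
    reference: str,
    nutrients=None,
) -> pd.Series:
    """Population-weighted mean per-capita reference intake per nutrient.

    ``dri`` is tidy with columns (nutrient, age_group, sex, reference,
    value); ``structure`` has columns (age_group, sex, proportion) for a
    single region and year, with proportions summing to one.
    """
    if reference not in VALID_REFERENCES:
        raise ConfigurationError(f"unknown reference type {reference!r}")
    total = structure["proportion"].sum()
    if abs(total - 1.0) > 1e-9:
        raise DataError(f"stratum proportions sum to {total}, expected 1")
    table = dri[dri["reference"] == reference]
    if nutrients is None:
        nutrients = sorted(table["nutrient"].unique(), key=_nutrient_order)
    out = {}
    for nutrient in nutrients:
        if reference not in references_for(nutrient):
            raise ConfigurationError(
                f"reference {reference} is not defined for nutrient {nutrient!r}"
            )
        rows = table[table["nutrient"] == nutrient]
        merged = structure.merge(rows, on=["age_group", "sex"], how="left")
        if merged["value"].isna().any():
            missing = merged.loc[merged["value"].isna(), ["age_group", "sex"]]
            raise DataError(
                f"missing {reference} rows for {nutrient}: "
                + ", ".join(f"{a}/{s}" for a, s in missing.itertuples(index=False))
            )
        out[nutrient] = float((merged["value"] * merged["proportion"]).sum())
    return pd.Series(out, name=reference)


def population_requirement(
    dri: pd.DataFrame,
    structure: pd.DataFrame,
    population: float,
    reference: str,
    nutrients=None,
) -> pd.Series:
    """Total daily requirement ``mu`` per nutrient for the whole population."""
    if population <= 0:
        raise DataError("population must be positive")
    return per_capita_requirement(dri, structure, reference, nutrients) * population


def requirement_bundle(
    dri: pd.DataFrame,
    structure: pd.DataFrame,
    population: float,
) -> pd.DataFrame:
    """``mu`` for every nutrient under every applicable reference type.

    Returns a DataFrame indexed by nutrient with one column per reference
    (EAR, RNI, AI, EER); entries are NaN where a reference does not apply.
    """
    present = set(dri["nutrient"].unique())
    columns = {}
    for reference in VALID_REFERENCES:
        nutrients = [n for n in present if reference in references_for(n)]
        if nutrients:
            columns[reference] = population_requirement(
                dri, structure, population, reference, sorted(nutrients, key=_nutrient_order)
            )
    out = pd.DataFrame(columns)
    out.index.name = "nutrient"
    return out


def _nutrient_order(name: str):
    try:
        return (0, NUTRIENTS.index(name))
    except ValueError:
        return (1, name)
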