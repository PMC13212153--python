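"""Uncertainty assessment: Monte Carlo over composition aggregation and a
production sensitivity sweep.

Food-composition tables resolve individual food items, while production
statistics only resolve aggregated groups; the representative group-level
content is therefore uncertain.  The Monte Carlo draws, in each run and
for each aggregated group, the content vector of one uniformly chosen
member item, substitutes it for the group value and recomputes baseline
coverage.  The sensitivity sweep rescales one crop's production (default
the vegetable aggregate, the input with the largest cross-source
discrepancies) over +-20% in 2% increments and recomputes coverage at each
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import requirements, scenarios
from .datasets import FoodSystemDataset
from .errors import ConfigurationError, DataError
from .foods import VEGETABLES_TOTAL, references_for
from .scenarios import ScenarioConfig

__all__ = [
    "MonteCarloConfig",
    "SensitivityConfig",
    "MonteCarloResult",
    "monte_carlo_coverage",
    "production_sensitivity",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    """Run count, seed and the reference used for the shortfall probability."""

    n_runs: int = 1000
    seed: int = 0
    threshold_reference: str = "EAR"

    def __post_init__(self):
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be at least 1")
        if self.threshold_reference not in ("EAR", "RNI"):
            raise ConfigurationError("threshold_reference must be EAR or RNI")


@dataclass(frozen=True)
class SensitivityConfig:
    """Target crop and sweep geometry (half-range and step, as fractions)."""

    target_crop: str = VEGETABLES_TOTAL
    half_range: float = 0.20
    step: float = 0.02

    def __post_init__(self):
        if self.step <= 0 or self.half_range <= 0:
            raise ConfigurationError("step and half_range must be positive")
        n = self.half_range / self.step
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("step must divide half_range evenly")

    @property
    def levels(self) -> np.ndarray:
        n = int(round(self.half_range / self.step))
        return np.round(np.arange(-n, n + 1) * self.step, 10)


@dataclass
class MonteCarloResult:
    """Per-run coverages and a per-nutrient summary."""

    runs: pd.DataFrame  # (run, nutrient, reference, coverage)
    summary: pd.DataFrame  # (nutrient, reference, mean, q05, q50, q95, p_below_1)
    seed: int


def _baseline_components(data: FoodSystemDataset, config: ScenarioConfig, year: int):
    """Fixed parts of the baseline coverage: form supplies, mu, animal supply."""
    transformed = scenarios.apply_scenario(data, config)
    form_supply = scenarios.compute_form_supply(transformed, config, year, "national")
    population = transformed.population_for(year)
    structure = transformed.structure_for(year)
    mu = requirements.requirement_bundle(transformed.dri, structure, population)
    animal = None
    if config.animal_foods != "none":
        animal = scenarios.animal_nutrient_supply(
            transformed.animal_intake, transformed.animal_composition, population
        )
    return transformed, form_supply, mu, animal


def monte_carlo_coverage(
    data: FoodSystemDataset,
    mc: MonteCarloConfig = MonteCarloConfig(),
    scenario: ScenarioConfig | str = "S1",
    year: int | None = None,
) -> MonteCarloResult:
    """Coverage distribution under member-level composition uncertainty.

    Supply-chain quantities and requirements are fixed; only the content
    vector of each aggregated group varies between runs, by substituting a
    uniformly drawn member item.  Groups with a single member are constant
    across runs, so a dataset of singleton groups collapses onto the
    deterministic point estimate.
    """
    if isinstance(scenario, str):
        scenario = ScenarioConfig.from_id(scenario)
    year = year if year is not None else data.years[-1]
    transformed, form_supply, mu, animal = _baseline_components(data, scenario, year)

    members = transformed.members
    if members.empty:
        raise DataError("no member-level composition data for the Monte Carlo")
    nutrients = sorted(transformed.composition["nutrient"].unique(), key=list(data.composition["nutrient"].unique()).index)
    member_matrix: dict[str, np.ndarray] = {}
    group_order = sorted(form_supply.index)
    for group in group_order:
        rows = members[members["group"] == group]
        if rows.empty:
            raise DataError(f"no member items for aggregated group {group!r}")
        wide = rows.pivot(index="member", columns="nutrient", values="content")
        member_matrix[group] = wide[nutrients].to_numpy(dtype=float)

    supply_vec = form_supply[group_order].to_numpy(dtype=float)
    animal_vec = (
        animal.reindex(nutrients).fillna(0.0).to_numpy(dtype=float)
        if animal is not None
        else np.zeros(len(nutrients))
    )
    mu_by_ref = {
        ref: mu[ref].reindex(nutrients).to_numpy(dtype=float) if ref in mu.columns else None
        for ref in ("EAR", "RNI", "AI", "EER")
    }

    rng = np.random.default_rng(mc.seed)
    counts = np.array([member_matrix[g].shape[0] for g in group_order])
    records = []
    for run in range(mc.n_runs):
        picks = rng.integers(0, counts)
        content = np.stack([member_matrix[g][k] for g, k in zip(group_order, picks)])
        total_supply = supply_vec @ content + animal_vec
        for j, nutrient in enumerate(nutrients):
            for ref in references_for(nutrient):
                mu_vec = mu_by_ref[ref]
                if mu_vec is None or np.isnan(mu_vec[j]):
                    raise DataError(f"no {ref} requirement for {nutrient}")
                records.append((run, nutrient, ref, total_supply[j] / mu_vec[j]))
    runs = pd.DataFrame(records, columns=["run", "nutrient", "reference", "coverage"])

    summary = (
        runs.groupby(["nutrient", "reference"])["coverage"]
        .agg(
            mean="mean",
            q05=lambda s: s.quantile(0.05),
            q50="median",
            q95=lambda s: s.quantile(0.95),
            p_below_1=lambda s: float((s < 1.0).mean()),
        )
        .reset_index()
    )
    return MonteCarloResult(runs=runs, summary=summary, seed=mc.seed)


def production_sensitivity(
    data: FoodSystemDataset,
    config: SensitivityConfig = SensitivityConfig(),
    scenario: ScenarioConfig | str = "S1",
    year: int | None = None,
) -> pd.DataFrame:
    """Baseline coverage per adjustment level of the target crop's production.

    Returns a tidy table (delta, nutrient, reference, coverage, diversity)
    with 21 levels for the default +-20% / 2% geometry; the zero level
    reproduces the unperturbed baseline.
    """
    if isinstance(scenario, str):
        scenario = ScenarioConfig.from_id(scenario)
    year = year if year is not None else data.years[-1]
    if config.target_crop not in set(data.production["crop"]):
        raise DataError(f"target crop {config.target_crop!r} absent from production table")
    frames = []
    for delta in config.levels:
        perturbed = data.copy()
        mask = perturbed.production["crop"] == config.target_crop
        perturbed.production.loc[mask, "tonnes"] *= 1.0 + delta
        results = scenarios.run_pipeline(perturbed, scenario, years=[year])
        results = results[["nutrient", "reference", "coverage", "diversity"]].assign(delta=delta)
        frames.append(results)
    out = pd.concat(frames, ignore_index=True)
    return out[["delta", "nutrient", "reference", "coverage", "diversity"]]
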