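"""Summary tables and plots from pipeline results.

Three reporting products mirror the standard presentation of this kind of
analysis: a coverage-versus-diversity scatter table per scenario, the
percent contribution of each source to a nutrient's plant-based coverage
(independent of the reference intake used, since the requirement cancels
in the shares), and a per-region band summary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError

__all__ = [
    "contribution_shares",
    "band_summary",
    "coverage_diversity_table",
    "plot_coverage_diversity",
]


def contribution_shares(nutrient_supply: pd.DataFrame) -> pd.DataFrame:
    """Percent contribution of each source to each nutrient's supply.

    ``nutrient_supply`` is the per-source nutrient-supply matrix returned
    with ``run_pipeline(..., return_networks=True)``; columns sum to 100
    for every nutrient with any supply.
    """
    totals = nutrient_supply.sum(axis=0)
    if (totals <= 0).all():
        raise DataError("no nutrient has positive supply")
    return nutrient_supply.div(totals, axis=1) * 100.0


def band_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Count of nutrients per coverage band for each scenario-region-year."""
    if results.empty:
        raise DataError("empty results table")
    per_nutrient = results.drop_duplicates(["scenario", "region", "year", "nutrient"])
    out = (
        per_nutrient.groupby(["scenario", "region", "year", "band"])["nutrient"]
        .count()
        .rename("n_nutrients")
        .reset_index()
    )
    return out


def coverage_diversity_table(results: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """Scatter-ready tidy table of coverage vs diversity per nutrient.

    With ``reference`` given ('EAR' or 'RNI'), keeps that reference for the
    EAR/RNI nutrients and the single AI/EER rows for potassium and energy.
    """
    if results.empty:
        raise DataError("empty results table")
    if reference is None:
        return results.copy()
    keep = results["reference"].isin([reference, "AI", "EER"])
    return results[keep].reset_index(drop=True)


def plot_coverage_diversity(results: pd.DataFrame, path: str | Path, reference: str = "EAR"):
    """Scatter plot of coverage against source diversity, one point per nutrient."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = coverage_diversity_table(results, reference)
    colors = {"high": "tab:green", "medium": "tab:orange", "low": "tab:red"}
    fig, ax = plt.subplots(figsize=(7, 5))
    for band, group in table.groupby("band"):
        ax.scatter(group["coverage"], group["diversity"], label=band,
                   color=colors.get(band, "tab:gray"), s=30)
        for row in group.itertuples():
            ax.annotate(row.nutrient, (row.coverage, row.diversity), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.axvline(1.0, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel(f"coverage (supply/requirement, {reference} basis)")
    ax.set_ylabel("source diversity (effective sources)")
    ax.legend(title="band")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
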