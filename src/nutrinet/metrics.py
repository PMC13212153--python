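"""Coverage and source-diversity statistics on the crop-nutrient network.

For nutrient ``j`` in year ``t`` the bipartite network carries edge weights

    W_tij = S_ti * n_ij / mu_tj

(the supply/demand ratio contributed by source ``i``).  Two summary
statistics follow:

* coverage ``NC_tj = sum_i W_tij`` — total supply relative to the
  population requirement (dimensionless; 1 means exactly sufficient);
* source diversity ``SD_tj = exp(-sum_i e_i ln e_i)`` with
  ``e_i = W_i / NC`` — the exponentiated Shannon entropy of proportional
  contributions, i.e. the effective number of equally important sources.
  It equals 1 for a single source, n for n equal sources, and is invariant
  to uniform rescaling of the weights (hence independent of which reference
  intake defines ``mu``).

Coverage is banded high/medium/low: for nutrients with both EAR and RNI,
high means supply >= RNI, medium EAR <= supply < RNI, low supply < EAR.
For AI/EER-based nutrients (potassium, energy): above the reference is
high, 80-100% medium, below 80% low.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "edge_weights",
    "coverage",
    "proportional_contributions",
    "shannon_entropy",
    "source_diversity",
    "classify_coverage",
    "build_network",
]


def edge_weights(nutrient_supply, mu):
    """Edge weights ``W = supply / mu`` (element-wise; ``mu`` must be > 0)."""
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr <= 0):
        raise DomainError("population requirement mu must be positive")
    supply = np.asarray(nutrient_supply, dtype=float)
    if np.any(supply < 0):
        raise DomainError("nutrient supplies must be non-negative")
    result = supply / mu_arr
    if isinstance(nutrient_supply, pd.DataFrame):
        return pd.DataFrame(result, index=nutrient_supply.index, columns=nutrient_supply.columns)
    if isinstance(nutrient_supply, pd.Series):
        return pd.Series(result, index=nutrient_supply.index)
    return result


def coverage(weights) -> float:
    """Coverage ``NC``: the sum of edge weights over sources."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise DomainError("edge weights must be non-negative")
    return float(w.sum())


def proportional_contributions(weights) -> np.ndarray:
    """Shares ``e_i = W_i / sum(W)``; requires a positive total."""
    w = np.asarray(weights, dtype=float)
    total = coverage(w)
    if total == 0.0:
        raise DomainError("proportional contributions undefined for zero coverage")
    return w / total


def shannon_entropy(weights) -> float:
    """Shannon entropy (nats) of the proportional contributions.

    Zero-share terms contribute nothing (the 0*ln(0) := 0 convention).
    """
    e = proportional_contributions(weights)
    positive = e[e > 0]
    return float(-(positive * np.log(positive)).sum())


def source_diversity(weights) -> float:
    """Effective number of sources, ``exp`` of the Shannon entropy.

    Returns NaN when total coverage is zero (diversity undefined, recorded
    as missing rather than raised).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise DomainError("edge weights must be non-negative")
    if w.sum() == 0.0:
        return float("nan")
    return float(np.exp(shannon_entropy(w)))


def classify_coverage(
    nc_ear: float | None = None,
    nc_rni: float | None = None,
    nc: float | None = None,
    kind: str = "EAR_RNI",
) -> str:
    """Band a nutrient's coverage as ``high``, ``medium`` or ``low``.

    ``kind='EAR_RNI'`` uses the two coverages against EAR and RNI; the
    AI/EER kinds use a single coverage with the 80%/100% thresholds
    (exactly 1.0 or exactly 0.8 fall in the medium band, following the
    wording "above AI or EER" for high and "80-100%" for medium).
    """
    if kind == "EAR_RNI":
        if nc_ear is None or nc_rni is None:
            raise DomainError("EAR_RNI classification needs both coverages")
        if nc_ear < 0 or nc_rni < 0:
            raise DomainError("coverage must be non-negative")
        if nc_rni >= 1.0:
            return "high"
        if nc_ear >= 1.0:
            return "medium"
        return "low"
    if kind in ("AI", "EER"):
        if nc is None:
            raise DomainError(f"{kind} classification needs a single coverage")
        if nc < 0:
            raise DomainError("coverage must be non-negative")
        if nc > 1.0:
            return "high"
        if nc >= 0.8:
            return "medium"
        return "low"
    raise DomainError(f"unknown classification kind {kind!r}")


def build_network(nutrient_supply: pd.DataFrame, mu: pd.Series) -> pd.DataFrame:
    """Edge-weight matrix W (source x nutrient) from supplies and ``mu``.

    ``nutrient_supply`` is indexed by source with nutrient columns;
    ``mu`` is indexed by nutrient (units/day, same units per column).
    """
    mu = mu.reindex(nutrient_supply.columns)
    if mu.isna().any():
        missing = list(mu.index[mu.isna()])
        raise DomainError(f"missing population requirement for {missing}")
    return edge_weights(nutrient_supply, mu.to_numpy())
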