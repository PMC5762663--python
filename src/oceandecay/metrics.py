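"""Community beta-diversity and environmental distance metrics.

Similarity between two stations is the Jaccard index on presence-absence
data, J = a / (a + b + c), where a counts shared taxa and b, c the taxa
private to each station. Environmental distance is the Euclidean distance
over z-scored variables, so every variable enters with equal weight. BIOENV
searches, by exhaustive subset enumeration, for the set of environmental
variables whose distances best rank-correlate (Spearman) with the community
dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .pairwise import PairwiseMatrix

__all__ = [
    "jaccard_matrix",
    "env_distance_matrix",
    "bioenv_select",
    "BioenvResult",
]


def jaccard_matrix(community: pd.DataFrame) -> PairwiseMatrix:
    """Pairwise Jaccard similarity between station rows of a 0/1 table.

    Pairs of stations that share no taxa and have none apiece (a+b+c = 0)
    have an undefined similarity and are returned as NaN; downstream
    pairwise analyses drop them.

    Raises
    ------
    ValueError
        If the table is not binary or has fewer than two stations.
    """
    X = community.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 stations for pairwise similarity")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("community matrix must be binary presence-absence")
    X = X.astype(float)
    a = X @ X.T                                  # shared taxa
    occupancy = X.sum(axis=1)
    union = occupancy[:, None] + occupancy[None, :] - a   # a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, a / union, np.nan)
    np.fill_diagonal(J, 1.0)
    return PairwiseMatrix(J, list(community.index.astype(str)), kind="similarity")


def zscore_columns(stations: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Z-score ((x - mean)/sd, sample sd) the selected variable columns."""
    missing = [v for v in variables if v not in stations.columns]
    if missing:
        raise ValueError(f"variables not in station table: {missing}")
    sub = stations[variables].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing values in selected environmental variables")
    sd = sub.std(ddof=1)
    flat = [v for v in variables if not sd[v] > 0]
    if flat:
        raise ValueError(f"zero-variance environmental variable(s): {flat}")
    return (sub - sub.mean()) / sd


def env_distance_matrix(
    stations: pd.DataFrame, variables: list[str]
) -> PairwiseMatrix:
    """Euclidean distance over z-scored environmental variables.

    ``stations`` must have a ``station`` column plus the named variables.
    """
    if len(variables) == 0:
        raise ValueError("need at least one environmental variable")
    Z = zscore_columns(stations, variables).to_numpy()
    from scipy.spatial.distance import squareform

    D = squareform(pdist(Z, metric="euclidean"))
    return PairwiseMatrix(D, list(stations["station"].astype(str)), kind="distance")


@dataclass
class BioenvResult:
    subset: tuple[str, ...]
    rho: float
    table: pd.DataFrame  # one row per evaluated subset: variables, size, rho


def bioenv_select(
    community_dissim: PairwiseMatrix,
    stations: pd.DataFrame,
    candidates: list[str],
    max_subset: int | None = None,
) -> BioenvResult:
    """Exhaustive BIOENV search over environmental-variable subsets.

    Every non-empty subset of ``candidates`` up to ``max_subset`` variables
    is scored by the Spearman rank correlation between its z-scored Euclidean
    distances and the community dissimilarities (upper triangles). Ties in
    rho are broken toward the smaller subset, then lexicographically.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate variable")
    if max_subset is None:
        max_subset = len(candidates)
    if max_subset > len(candidates):
        warnings.warn(
            f"max_subset={max_subset} exceeds number of candidates; clipping",
            stacklevel=2,
        )
        max_subset = len(candidates)

    labels = list(stations["station"].astype(str))
    dissim = community_dissim.reorder(labels).condensed()
    keep = np.isfinite(dissim)

    # z-score once; subset distances are Euclidean over column slices
    Z = zscore_columns(stations, candidates).to_numpy()
    rows = []
    for size in range(1, max_subset + 1):
        for combo in combinations(range(len(candidates)), size):
            d = pdist(Z[:, combo], metric="euclidean")
            rho = spearmanr(d[keep], dissim[keep]).statistic
            rows.append(
                {
                    "variables": tuple(candidates[i] for i in combo),
                    "size": size,
                    "rho": float(rho),
                }
            )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (-rows[i]["rho"], rows[i]["size"], rows[i]["variables"]),
    )
    best = rows[order[0]]
    return BioenvResult(subset=best["variables"], rho=best["rho"], table=table)
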