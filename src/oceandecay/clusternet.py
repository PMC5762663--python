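"""Biogeographic station clustering and similarity networks.

Stations are grouped by hierarchical (default UPGMA) clustering of the
Jaccard distance matrix; the number of clusters is chosen as the largest k
whose grouping is significant under ANOSIM at a configurable level. A
similarity network keeps edges above the largest threshold that still
leaves every node with a prescribed minimum degree; node degree then plays
the role of station connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .matrixstats import AnosimResult, anosim
from .pairwise import PairwiseMatrix

__all__ = [
    "ClusterAssignment",
    "hierarchical_clusters",
    "select_cluster_count",
    "build_network",
    "network_edge_list",
]


@dataclass
class ClusterAssignment:
    labels: dict[str, int]          # station -> cluster id (1-based)
    k: int
    linkage_method: str
    anosim: AnosimResult | None = None
    no_significant_k: bool = False
    selection_policy: str = "largest significant k"

    def label_array(self, stations: list[str]) -> np.ndarray:
        return np.asarray([self.labels[s] for s in stations])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"station": s, "cluster": c} for s, c in self.labels.items()]
        df = pd.DataFrame(rows)
        if self.anosim is not None:
            df["anosim_R"] = self.anosim.R
            df["anosim_p"] = self.anosim.p
        return df


def hierarchical_clusters(
    dissim: PairwiseMatrix, k: int, linkage_method: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of stations cut at k clusters.

    Deterministic given the linkage method; scipy breaks merge ties by
    cluster index order.
    """
    if not 1 <= k <= dissim.n:
        raise ValueError(f"k must lie in [1, {dissim.n}], got {k}")
    Z = linkage(dissim.condensed(), method=linkage_method)
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=dict(zip(dissim.labels, (int(c) for c in flat))),
        k=int(len(np.unique(flat))),
        linkage_method=linkage_method,
    )


def _clustered_anosim_R(condensed: np.ndarray, k: int, method: str) -> float:
    """ANOSIM R of the k-cluster partition of a condensed matrix.

    Returns -inf when the partition has a singleton cluster (ANOSIM on such
    a grouping is not accepted downstream), so the statistic is comparable
    between the observed matrix and shuffled surrogates.
    """
    from scipy.stats import rankdata

    Z = linkage(condensed, method=method)
    lab = fcluster(Z, t=k, criterion="maxclust")
    counts = np.bincount(lab)
    if len(np.unique(lab)) < 2 or (counts[counts > 0] < 2).any():
        return -np.inf
    n = len(lab)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(condensed)
    within = lab[iu] == lab[ju]
    if not within.any() or within.all():
        return -np.inf
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def select_cluster_count(
    dissim: PairwiseMatrix,
    k_range=None,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Pick the largest k whose clustering is ANOSIM-significant.

    Because the candidate grouping is derived from the very matrix being
    tested, a plain label-permutation ANOSIM p-value is strongly
    anticonservative (the clustering maximizes exactly the within/between
    contrast ANOSIM measures). Significance is therefore assessed against a
    matrix-shuffle null: surrogate matrices with the condensed
    dissimilarities randomly shuffled are re-clustered and re-scored, and
    p = (1 + #{surrogate R >= observed R}) / (1 + n_perm). Under an
    exchangeable-noise null this is exact; for strongly metric data it is
    approximate (shuffled surrogates are not metric). The reported
    ``anosim`` field still carries the descriptive label-permutation test.
    Returns k = 1 with a flag when no k is significant at ``alpha``.
    """
    n = dissim.n
    if k_range is None:
        k_range = range(2, n)
    condensed = dissim.condensed()
    rng = np.random.default_rng(seed)
    shuffles = [rng.permutation(condensed) for _ in range(n_perm)]
    best: ClusterAssignment | None = None
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k_range values must lie in [2, {n - 1}]")
        r_obs = _clustered_anosim_R(condensed, k, linkage_method)
        if not np.isfinite(r_obs):
            continue
        hits = sum(
            _clustered_anosim_R(s, k, linkage_method) >= r_obs for s in shuffles
        )
        p = (1 + hits) / (1 + n_perm)
        if p <= alpha:
            assign = hierarchical_clusters(dissim, k, linkage_method)
            lab = assign.label_array(dissim.labels)
            assign.anosim = anosim(dissim, lab, n_perm=n_perm, seed=seed)
            assign.selection_policy = (
                f"largest k with matrix-shuffle p <= {alpha} (p={p:.4g})"
            )
            best = assign
    if best is None:
        assign = hierarchical_clusters(dissim, 1, linkage_method)
        assign.no_significant_k = True
        return assign
    return best


def build_network(
    similarity: PairwiseMatrix,
    clusters: ClusterAssignment | None = None,
    min_degree: int = 1,
) -> nx.Graph:
    """Similarity network at the maximal threshold respecting min degree.

    The threshold is the largest similarity value such that every station
    keeps at least ``min_degree`` incident edges (edges with weight >=
    threshold are retained); equivalently, the minimum over stations of
    their ``min_degree``-th largest off-diagonal similarity. Lowering
    ``min_degree`` can only raise the threshold.
    """
    n = similarity.n
    if not 1 <= min_degree <= n - 1:
        raise ValueError(f"min_degree must lie in [1, {n - 1}]")
    S = similarity.values.copy().astype(float)
    np.fill_diagonal(S, -np.inf)
    S[~np.isfinite(S)] = -np.inf
    # per-station min_degree-th largest similarity; threshold = their minimum
    kth = np.sort(S, axis=1)[:, n - 1 - (min_degree - 1)]
    threshold = float(kth.min())
    G = nx.Graph(threshold=threshold, min_degree=min_degree)
    for i, lab in enumerate(similarity.labels):
        attrs = {}
        if clusters is not None:
            attrs["cluster"] = int(clusters.labels[lab])
        G.add_node(lab, **attrs)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = S[i, j]
        if w >= threshold:
            G.add_edge(similarity.labels[i], similarity.labels[j], weight=float(w))
    for node in G.nodes:
        G.nodes[node]["degree"] = G.degree(node)
    return G


def network_edge_list(G: nx.Graph) -> pd.DataFrame:
    """Edge list (source, target, weight) for TSV export."""
    return pd.DataFrame(
        [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in G.edges(data=True)
        ]
    )
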