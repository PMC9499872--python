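"""Clustering and typing of co-twin pairs on the trait-discordance matrix.

Pairs are clustered on z-scored discordances via a shared-nearest-neighbor
(SNN) graph with Jaccard edge weights and Louvain modularity optimization,
embedded in 2-D with UMAP for reporting, and each cluster is assigned a UPV
type (Concordant / TypeA / TypeB / Intermediate) from its centroid's mean
fat- and lean-trait discordances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from .cohort import DiscordanceMatrix
from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)

TYPES = ("Concordant", "TypeA", "TypeB", "Intermediate", "Unassigned")


def _zscore_columns(values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def snn_graph(X: np.ndarray, k_neighbors: int) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each point is connected to its ``k_neighbors`` Euclidean nearest
    neighbors (self included in the neighbor sets, as is conventional for
    SNN construction); edges are weighted by the Jaccard similarity of the
    two neighbor sets and kept only when positive.
    """
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise InsufficientDataError(
            f"insufficient pairs: {n} pairs for k_neighbors={k_neighbors}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row) for row in idx]  # row includes self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def cluster_cotwin_pairs(
    D: DiscordanceMatrix,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Louvain community labels for co-twin pairs (deterministic given seed).

    Columns are z-scored, a kNN graph (Euclidean) is converted to an SNN
    graph with Jaccard weights, and communities are found by modularity
    optimization at the given resolution.  ``k_neighbors`` is capped at a
    third of the pair count.
    """
    values = D.values
    if values.isna().any().any():
        raise ConfigurationError("discordance matrix has missing cells; filter first")
    n = len(values)
    if n < k_neighbors + 1:
        raise InsufficientDataError(
            f"insufficient pairs: {n} for k_neighbors={k_neighbors}"
        )
    k = max(2, min(k_neighbors, n // 3))
    X = _zscore_columns(values)
    g = snn_graph(X, k)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(n, dtype=int)
    # stable relabeling: clusters numbered by their smallest member index
    for cid, members in enumerate(sorted(communities, key=min)):
        for m in members:
            labels[m] = cid
    return pd.Series(labels, index=values.index, name="cluster")


def cluster_stability_null(
    D: DiscordanceMatrix,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    n_null: int = 20,
) -> dict:
    """Column-permutation null test for clustering structure.

    Each trait column is permuted independently across pairs (destroying
    inter-trait correlation, preserving marginals) and the full SNN+Louvain
    procedure re-run; the observed weighted modularity is compared with the
    null distribution.  Structure is called when the observed modularity
    exceeds every null replicate.  Returns observed/null modularities, the
    call, and the effective number of stable clusters (1 when no structure).
    """
    labels = cluster_cotwin_pairs(D, k_neighbors, resolution, seed)
    values = D.values
    n = len(values)
    k = max(2, min(k_neighbors, n // 3))
    X = _zscore_columns(values)
    g = snn_graph(X, k)
    parts = [set(np.nonzero(labels.to_numpy() == c)[0]) for c in np.unique(labels)]
    observed = nx.community.modularity(g, parts, weight="weight", resolution=resolution)
    rng = np.random.default_rng(seed)
    null_mod = []
    for _ in range(n_null):
        Xn = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        gn = snn_graph(Xn, k)
        cn = nx.community.louvain_communities(
            gn, weight="weight", resolution=resolution,
            seed=int(rng.integers(2**31 - 1)),
        )
        null_mod.append(
            nx.community.modularity(gn, cn, weight="weight", resolution=resolution)
        )
    stable = observed > max(null_mod)
    return {
        "labels": labels,
        "observed_modularity": float(observed),
        "null_modularities": [float(m) for m in null_mod],
        "stable": bool(stable),
        "n_stable_clusters": int(labels.nunique()) if stable else 1,
    }


def embed_pairs(
    D: DiscordanceMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D UMAP embedding of pairs, for reporting only.

    Cluster membership is never read off the embedding.  Deterministic
    given seed.
    """
    values = D.values
    if values.isna().any().any():
        raise ConfigurationError("discordance matrix has missing cells; filter first")
    if n_neighbors >= len(values):
        raise InsufficientDataError(
            f"n_neighbors={n_neighbors} must be < number of pairs ({len(values)})"
        )
    import umap  # deferred: numba compilation is slow at import

    X = _zscore_columns(values)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=values.index, columns=["x", "y"])


@dataclass
class UPVClustering:
    """Cluster labels, type map, centroids and optional embedding."""

    labels: pd.Series
    cluster_types: dict[int, str]
    centroids: pd.DataFrame
    embedding: pd.DataFrame | None = None
    parameters: dict = field(default_factory=dict)

    def type_of_pair(self, pair: str) -> str:
        return self.cluster_types[int(self.labels.loc[pair])]

    @property
    def pair_types(self) -> pd.Series:
        return self.labels.map(self.cluster_types).rename("type")


def assign_cluster_types(
    labels: pd.Series,
    D: DiscordanceMatrix,
    fat_traits,
    lean_traits,
    tau_lean: float | None = None,
) -> UPVClustering:
    """Assign UPV types to clusters from their centroid discordances.

    Per cluster: m_fat / m_lean = mean fat-/lean-trait discordance of the
    centroid, m_abs = mean |d| over all traits.  The cluster with minimal
    m_abs is Concordant; remaining clusters are TypeB (m_fat > 0 and
    m_lean >= tau_lean), TypeA (m_fat > 0 and m_lean <= 0), Intermediate
    (0 < m_lean < tau_lean) or Unassigned.  ``tau_lean`` defaults to half
    the cohort standard deviation of lean-trait discordances.
    """
    fat = [t for t in fat_traits if t in D.values.columns]
    lean = [t for t in lean_traits if t in D.values.columns]
    if not fat or not lean:
        raise ConfigurationError("no fat/lean trait tags present in the matrix")
    if tau_lean is None:
        tau_lean = 0.5 * float(D.values[lean].to_numpy().std(ddof=0))
    centroids = D.values.groupby(labels).mean()
    m_fat = centroids[fat].mean(axis=1)
    m_lean = centroids[lean].mean(axis=1)
    m_abs = centroids.abs().mean(axis=1)
    types: dict[int, str] = {}
    concordant = int(m_abs.idxmin())
    for cid in centroids.index:
        cid = int(cid)
        if cid == concordant:
            types[cid] = "Concordant"
            continue
        mf, ml = float(m_fat.loc[cid]), float(m_lean.loc[cid])
        if mf > 0 and ml >= tau_lean:
            types[cid] = "TypeB"
        elif mf > 0 and ml <= 0:
            types[cid] = "TypeA"
        elif 0 < ml < tau_lean:
            types[cid] = "Intermediate"
        else:
            types[cid] = "Unassigned"
    # TypeB is unique: of several qualifying clusters, the one with the
    # strongest coordinated fat+lean overgrowth keeps the label; the rest
    # tend toward TypeB and are relabelled Intermediate
    typeb = [c for c, t in types.items() if t == "TypeB"]
    if len(typeb) > 1:
        keep = max(typeb, key=lambda c: float(m_fat.loc[c] + m_lean.loc[c]))
        for c in typeb:
            if c != keep:
                types[c] = "Intermediate"
    return UPVClustering(
        labels=labels,
        cluster_types=types,
        centroids=centroids,
        parameters={"tau_lean": float(tau_lean)},
    )


@dataclass
class HeatmapOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    scaled: pd.DataFrame


def heatmap_order(D, scale_rows: bool = True) -> HeatmapOrder:
    """Hierarchical heat-map ordering (Euclidean, complete linkage).

    Rows are z-scaled (constant rows become zeros, with a warning), then
    rows and columns are clustered by complete-linkage agglomeration on
    Euclidean distances.  Accepts a DiscordanceMatrix or a plain DataFrame.
    """
    values = D.values if isinstance(D, DiscordanceMatrix) else D
    if values.isna().any().any():
        raise ConfigurationError("missing cells; filter first")
    X = values.to_numpy(dtype=float)
    if scale_rows:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        const = (sd == 0).ravel()
        if const.any():
            log.warning("%d constant rows scaled to zeros", int(const.sum()))
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    row_link = hierarchy.linkage(pdist(X), method="complete")
    row_order = [values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_link = None
    col_order = list(values.columns)
    if X.shape[1] > 1:
        col_link = hierarchy.linkage(pdist(X.T), method="complete")
        col_order = [values.columns[i] for i in hierarchy.leaves_list(col_link)]
    scaled = pd.DataFrame(X, index=values.index, columns=values.columns)
    return HeatmapOrder(row_order, col_order, row_link, col_link, scaled)
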