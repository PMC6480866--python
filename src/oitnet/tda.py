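"""Feature-network construction, clustering, and biomarker prioritization.

Features (not samples) are the nodes: pairwise Spearman rank correlation
over the pooled samples defines similarity, a mutual k-nearest-neighbor
rule (an edge only when each feature is among the other's k most similar)
defines the graph with k = ceil(ln n) following the connectivity argument
for kNN graphs, and multilevel modularity optimization (Louvain) assigns
clusters. Candidate biomarkers are then prioritized by their unweighted
shortest-path distance to the nearest clinical outcome feature: features
with no path are flagged unrelated, and same-cluster features with
identical closed neighborhoods are flagged redundant (they carry the same
topological information, so measuring one suffices).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd


def _multi_source_bfs(graph: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Unweighted shortest-path length from the nearest of ``sources``."""
    from collections import deque

    dist = {s: 0 for s in sources if s in graph}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


@dataclass
class SimilarityMatrix:
    """Feature x feature Spearman rho (symmetric, diagonal unused) and the
    sample count it was computed from."""

    rho: pd.DataFrame
    n_samples: int

    @property
    def features(self) -> list[str]:
        return list(self.rho.columns)


def choose_k(n: int) -> int:
    """Neighbor count for the mutual kNN graph: k = ceil(ln n).

    A kNN graph on n points is connected with high probability when k grows
    on the order of log n, so the natural-log ceiling is used, clamped to
    [1, n - 1]. For the 91-animal pooled CMA study this gives k = 5.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples to pick k, got {n}")
    return int(min(max(1, math.ceil(math.log(n))), n - 1))


def spearman_adjacency(pooled: pd.DataFrame, min_pairs: int = 3) -> SimilarityMatrix:
    """Spearman rank-correlation similarity over all feature pairs.

    Ranks use the average-rank convention for ties; missing values are
    dropped pairwise. Constant features (no rank information) are excluded
    with a warning; every retained pair must keep at least ``min_pairs``
    jointly observed samples.
    """
    numeric = pooled[[c for c in pooled.columns
                      if pd.api.types.is_numeric_dtype(pooled[c])]]
    nunique = numeric.nunique(dropna=True)
    constant = [c for c in numeric.columns if nunique[c] <= 1]
    if constant:
        warnings.warn(
            f"excluding constant feature(s) from similarity: {constant}",
            stacklevel=2,
        )
        numeric = numeric.drop(columns=constant)
    if numeric.shape[1] == 0:
        raise ValueError("all features are constant; no similarity to compute")

    observed = numeric.notna().astype(int)
    pair_counts = observed.T @ observed
    off_diag = pair_counts.to_numpy()[~np.eye(len(pair_counts), dtype=bool)]
    if len(off_diag) and off_diag.min() < min_pairs:
        raise ValueError(
            f"some feature pairs have fewer than {min_pairs} jointly "
            "observed samples"
        )
    rho = numeric.corr(method="spearman")
    return SimilarityMatrix(rho=rho, n_samples=len(numeric))


def mutual_knn_graph(
    sim: SimilarityMatrix, k: int, similarity: str = "signed"
) -> nx.Graph:
    """Mutual k-nearest-neighbor graph over features.

    An edge {u, v} exists iff v is among u's k most similar features AND u
    is among v's k most similar. ``similarity`` selects whether "nearest"
    means largest signed rho (default) or largest |rho| (anti-correlated
    features count as near). Similarity ties are broken by feature name
    (lexicographic), making the graph deterministic. Node degree is at most
    k by construction.
    """
    features = sim.features
    m = len(features)
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must be in [1, {m - 1}], got {k}")
    if similarity not in ("signed", "absolute"):
        raise ValueError("similarity must be 'signed' or 'absolute'")

    values = sim.rho.to_numpy(dtype=float)
    if similarity == "absolute":
        values = np.abs(values)

    neighbor_sets: dict[str, set[str]] = {}
    for i, f in enumerate(features):
        others = [(values[i, j], features[j]) for j in range(m) if j != i]
        # descending similarity, ties by name ascending
        others.sort(key=lambda t: (-t[0], t[1]))
        neighbor_sets[f] = {name for _, name in others[:k]}

    g = nx.Graph(k=k, similarity=similarity)
    g.add_nodes_from(features)
    for i, u in enumerate(features):
        for v in features[i + 1:]:
            if v in neighbor_sets[u] and u in neighbor_sets[v]:
                g.add_edge(u, v, rho=float(sim.rho.loc[u, v]))
    return g


def louvain_partition(
    graph: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> nx.Graph:
    """Cluster the feature graph by multilevel modularity optimization.

    Runs the Louvain multilevel algorithm (via igraph) on the unweighted
    graph; the node-sweep order is randomized, so the partition is seeded
    for reproducibility. An edgeless graph yields singleton clusters.
    Returns a copy of the graph with an integer ``cluster`` attribute per
    node; cluster ids are relabeled so that cluster 0 is the largest.
    """
    out = graph.copy()
    nodes = sorted(out.nodes)
    if out.number_of_edges() == 0:
        for i, n in enumerate(nodes):
            out.nodes[n]["cluster"] = i
        return out

    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in out.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    state = random.getstate()
    try:
        random.seed(seed)
        clustering = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)

    membership = np.asarray(clustering.membership)
    # deterministic relabel: by decreasing size, ties by smallest member name
    sizes: dict[int, int] = {}
    first: dict[int, str] = {}
    for n, c in zip(nodes, membership):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, n)
    order = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    relabel = {c: i for i, c in enumerate(order)}
    for n in nodes:
        out.nodes[n]["cluster"] = relabel[membership[index[n]]]
    return out


def set_distance(graph: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Minimum unweighted shortest-path length between two node sets.

    Returns 0 when the sets share a node and ``inf`` when no path exists.
    """
    a = [n for n in set_a if n in graph]
    b = {n for n in set_b if n in graph}
    if not a or not b:
        return float("inf")
    if b.intersection(a):
        return 0.0
    lengths = _multi_source_bfs(graph, a)
    best = min((d for n, d in lengths.items() if n in b), default=float("inf"))
    return float(best)


@dataclass
class PrioritizationReport:
    """Per-feature distance-to-clinical ranking plus per-cluster summary."""

    features: pd.DataFrame  # cluster, distance, rank, unrelated, redundant
    clusters: pd.DataFrame  # size, clinical_members, distance_to_clinical_cluster
    clinical: list[str]

    def to_csv(self, path) -> None:
        self.features.to_csv(path, float_format="%.6f")

    def to_json(self, path) -> None:
        import json

        payload = {
            "clinical": self.clinical,
            "features": {
                f: {
                    "cluster": int(r["cluster"]),
                    "distance": (None if np.isinf(r["distance"])
                                 else float(r["distance"])),
                    "rank": int(r["rank"]),
                    "unrelated": bool(r["unrelated"]),
                    "redundant": bool(r["redundant"]),
                }
                for f, r in self.features.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")


def prioritize_features(
    graph: nx.Graph, clinical: Sequence[str]
) -> PrioritizationReport:
    """Rank features by graph proximity to the clinical outcome features.

    Distance is the unweighted shortest-path length (edge count) to the
    nearest clinical feature (clinical features themselves are at distance
    0); features with no path are flagged ``unrelated`` ("of lesser
    importance" in prioritization terms) and rank last. Within a cluster,
    features with identical closed neighborhoods are interchangeable
    topologically and are flagged ``redundant``.

    Requires a ``cluster`` node attribute (see :func:`louvain_partition`).
    """
    clinical_present = [c for c in clinical if c in graph]
    if not clinical_present:
        raise ValueError("no clinical feature is present in the graph")
    if any("cluster" not in graph.nodes[n] for n in graph.nodes):
        raise ValueError("graph lacks cluster assignment; run louvain_partition first")

    lengths = _multi_source_bfs(graph, clinical_present)
    nodes = sorted(graph.nodes)
    dist = {n: float(lengths.get(n, np.inf)) for n in nodes}

    # redundancy: identical closed neighborhoods within the same cluster
    signature: dict[str, tuple] = {}
    for n in nodes:
        closed = frozenset(graph.neighbors(n)) | {n}
        signature[n] = (graph.nodes[n]["cluster"], closed)
    counts: dict[tuple, int] = {}
    for sig in signature.values():
        counts[sig] = counts.get(sig, 0) + 1
    redundant = {n: counts[signature[n]] > 1 for n in nodes}

    ordered = sorted(nodes, key=lambda n: (dist[n], n))
    rank = {n: i + 1 for i, n in enumerate(ordered)}
    features = pd.DataFrame(
        {
            "cluster": [graph.nodes[n]["cluster"] for n in nodes],
            "distance": [dist[n] for n in nodes],
            "rank": [rank[n] for n in nodes],
            "unrelated": [np.isinf(dist[n]) for n in nodes],
            "redundant": [redundant[n] for n in nodes],
        },
        index=pd.Index(nodes, name="feature"),
    )

    cluster_ids = sorted({graph.nodes[n]["cluster"] for n in nodes})
    members = {c: [n for n in nodes if graph.nodes[n]["cluster"] == c]
               for c in cluster_ids}
    clin_count = {c: sum(n in clinical_present for n in members[c])
                  for c in cluster_ids}
    clinical_cluster = max(cluster_ids, key=lambda c: (clin_count[c], -c))
    clusters = pd.DataFrame(
        {
            "size": [len(members[c]) for c in cluster_ids],
            "clinical_members": [clin_count[c] for c in cluster_ids],
            "distance_to_clinical_cluster": [
                set_distance(graph, members[c], members[clinical_cluster])
                for c in cluster_ids
            ],
        },
        index=pd.Index(cluster_ids, name="cluster"),
    )
    return PrioritizationReport(
        features=features, clusters=clusters, clinical=clinical_present
    )
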