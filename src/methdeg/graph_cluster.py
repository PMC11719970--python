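"""Cosine-KNN similarity graphs, Louvain communities and the K-scan.

Each sample becomes a node; edges connect it to its K most cosine-similar
peers (union-symmetrized, deterministic tie-break by similarity then id).
Edges with non-positive similarity are dropped — modularity on negative
weights is ill-defined.  The K-scan sweeps K over a range and reports the
smallest K at which the community count holds constant over a trailing
window, the "stabilized" configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    k: int

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass
class CommunityAssignment:
    membership: dict  # sample_id -> community index (contiguous from 0)
    n_communities: int
    modularity: float
    no_edges: bool = False

    def labels_for(self, sample_ids: Sequence) -> np.ndarray:
        return np.asarray([self.membership[s] for s in sample_ids])


@dataclass
class KScanResult:
    counts: dict  # K -> community count
    stable_k: int
    stable_count: int
    window: int
    stable: bool


def knn_similarity_graph(
    X: np.ndarray, K: int, sample_ids: Sequence | None = None
) -> SimilarityGraph:
    """Union-symmetrized K-nearest-neighbour cosine similarity graph."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    sample_ids = list(sample_ids)
    if K < 1 or n < K + 1:
        raise ValueError(f"need n_samples >= K+1 (n={n}, K={K})")
    norms = np.linalg.norm(X, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(
            f"cosine similarity undefined for zero-norm sample {sample_ids[zero[0]]!r}"
        )
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    g = nx.Graph()
    g.add_nodes_from(sample_ids)
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-S[i, j], str(sample_ids[j])),
        )
        # neighbours exactly tied with the K-th similarity are all kept, so
        # e.g. identical vectors at K=1 still form their full clique
        cutoff = S[i, order[K - 1]]
        chosen = order[:K] + [j for j in order[K:] if S[i, j] == cutoff]
        for j in chosen:
            w = float(S[i, j])
            if w <= 0.0:
                continue
            if not g.has_edge(sample_ids[i], sample_ids[j]):
                g.add_edge(sample_ids[i], sample_ids[j], weight=w)
    return SimilarityGraph(graph=g, k=K)


def weighted_modularity(g: nx.Graph, membership: dict, resolution: float = 1.0) -> float:
    """Standard weighted Newman modularity, computed from first principles."""
    m2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    if m2 == 0:
        return 0.0
    deg = dict(g.degree(weight="weight"))
    q = 0.0
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            q += 2.0 * d.get("weight", 1.0)
    q /= m2
    comm_deg: dict = {}
    for node, c in membership.items():
        comm_deg[c] = comm_deg.get(c, 0.0) + deg.get(node, 0.0)
    q -= resolution * sum((dc / m2) ** 2 for dc in comm_deg.values())
    return q


def louvain_partition(
    g: SimilarityGraph | nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityAssignment:
    """Seeded weighted-modularity Louvain partition with contiguous indices."""
    graph = g.graph if isinstance(g, SimilarityGraph) else g
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    no_edges = graph.number_of_edges() == 0
    if no_edges:
        communities = [{node} for node in graph.nodes]
    else:
        communities = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed
        )
    # deterministic contiguous indexing: order communities by smallest member id
    ordered = sorted(communities, key=lambda c: min(map(str, c)))
    membership = {
        node: idx
        for idx, comm in enumerate(ordered)
        for node in sorted(comm, key=str)
    }
    return CommunityAssignment(
        membership=membership,
        n_communities=len(ordered),
        modularity=weighted_modularity(graph, membership, resolution),
        no_edges=no_edges,
    )


def k_scan(
    X: np.ndarray,
    k_min: int = 1,
    k_max: int = 50,
    window: int = 4,
    resolution: float = 1.0,
    seed: int = 0,
    sample_ids: Sequence | None = None,
) -> KScanResult:
    """Community count per K plus the smallest K with a flat trailing window."""
    X = np.asarray(X, dtype=float)
    if k_max >= X.shape[0]:
        raise ValueError(f"k_max ({k_max}) must be below n_samples ({X.shape[0]})")
    counts = {}
    for K in range(k_min, k_max + 1):
        g = knn_similarity_graph(X, K, sample_ids)
        counts[K] = louvain_partition(g, resolution, seed).n_communities
    stable_k, stable = find_stable_k(counts, window)
    return KScanResult(counts, stable_k, counts[stable_k], window, stable)


def find_stable_k(counts: dict, window: int) -> tuple[int, bool]:
    """Smallest K whose count is constant over the next ``window`` K values;
    falls back to the largest K with a False flag when no plateau exists."""
    ks = sorted(counts)
    for i, K in enumerate(ks):
        if i + window >= len(ks):
            break
        if all(counts[ks[i + d]] == counts[K] for d in range(1, window + 1)):
            return K, True
    return ks[-1], False
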