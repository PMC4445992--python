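"""From the optimized likelihood matrix to protein complexes.

Step two of the method extracts *base clusters*: an interaction {i, j}
qualifies when its optimized likelihood meets the threshold w_min, and a
depth-first search seeded at every protein collects the proteins reachable
over qualified interactions. After deduplication the base clusters are
exactly the connected components of the qualified-edge graph (singleton
seeds included until the size filter removes them).

Step three merges base clusters whose member overlap (Jaccard of the two
protein sets) reaches os_max, in single-link fashion: components of the
≥-threshold meta-graph are replaced by the union of their members. Overlap
scores are never recomputed against merged unions, which is what makes the
merge incremental and independent of input order.

W is not symmetrized during optimization, so a pair has two oriented
likelihoods; the default qualification rule takes their max (co-clustering
likelihood is conceptually symmetric), with min and mean selectable for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ClusterSet, PPINetwork

EDGE_RULES = ("max", "min", "mean")


@dataclass
class ClusterParams:
    w_min: float = 0.5
    os_max: float = 0.5
    min_size: int = 2
    edge_rule: str = "max"

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_min <= 1.0 and 0.0 <= self.os_max <= 1.0):
            raise ValueError("w_min and os_max must lie in [0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.edge_rule not in EDGE_RULES:
            raise ValueError(f"edge_rule must be one of {EDGE_RULES}")


def _pair_likelihood(W: np.ndarray, i: int, j: int, rule: str) -> float:
    a, b = W[i, j], W[j, i]
    if rule == "max":
        return max(a, b)
    if rule == "min":
        return min(a, b)
    return (a + b) / 2.0


def qualified_edges(
    W_star: np.ndarray,
    T: np.ndarray,
    w_min: float,
    edge_rule: str = "max",
) -> set[tuple[int, int]]:
    """Network edges {i, j} whose symmetrized likelihood meets w_min."""
    if edge_rule not in EDGE_RULES:
        raise ValueError(f"edge_rule must be one of {EDGE_RULES}")
    n = T.shape[0]
    out: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if T[i, j] and _pair_likelihood(W_star, i, j, edge_rule) >= w_min:
                out.add((i, j))
    return out


def _dfs(seed: int, adj: list[list[int]]) -> frozenset[int]:
    """Iterative depth-first search over qualified edges from one seed."""
    seen = {seed}
    stack = [seed]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(seen)


def extract_base_clusters(
    network: PPINetwork,
    W_star: np.ndarray,
    params: ClusterParams,
) -> ClusterSet:
    """Seed a DFS at every protein and keep the deduplicated clusters of at
    least ``params.min_size`` proteins."""
    edges = qualified_edges(W_star, network.T, params.w_min, params.edge_rule)
    adj: list[list[int]] = [[] for _ in range(network.n_V)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    clusters: list[frozenset[str]] = []
    seen: set[frozenset[int]] = set()
    for seed in range(network.n_V):
        component = _dfs(seed, adj)
        if component in seen or len(component) < params.min_size:
            continue
        seen.add(component)
        clusters.append(frozenset(network.proteins[i] for i in component))
    return ClusterSet(clusters=clusters, provenance="base")


def overlap_score(bc_p: frozenset | set, bc_q: frozenset | set) -> float:
    """Jaccard overlap |BC_p ∩ BC_q| / |BC_p ∪ BC_q| of two base clusters."""
    if not bc_p or not bc_q:
        raise ValueError("base clusters must be nonempty")
    inter = len(set(bc_p) & set(bc_q))
    return inter / (len(bc_p) + len(bc_q) - inter)


def merge_base_clusters(base: ClusterSet, os_max: float) -> ClusterSet:
    """Single-link merge: meta-graph components at overlap ≥ os_max collapse
    to the union of their members. Output order is canonical (sorted member
    tuples), so the result is invariant to the input ordering."""
    members = list(base)
    G = nx.Graph()
    G.add_nodes_from(range(len(members)))
    for p in range(len(members)):
        for q in range(p + 1, len(members)):
            if overlap_score(members[p], members[q]) >= os_max:
                G.add_edge(p, q)
    merged: list[frozenset[str]] = []
    for component in nx.connected_components(G):
        union: set[str] = set()
        for idx in component:
            union |= members[idx]
        merged.append(frozenset(union))
    merged.sort(key=lambda c: tuple(sorted(c)))
    return ClusterSet(clusters=merged, provenance="predicted")


def detect_complexes(
    network: PPINetwork,
    W_star: np.ndarray,
    params: ClusterParams,
) -> ClusterSet:
    """Convenience pipeline: extract base clusters, then merge them."""
    return merge_base_clusters(
        extract_base_clusters(network, W_star, params), params.os_max
    )
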