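"""Initial tree construction: affinity-propagation exemplars + Kruskal MST.

The elastic-graph optimization is greedy, so a good initial structure both
speeds up convergence and avoids poor local minima. Cells are first
summarized by affinity-propagation exemplars; a Euclidean minimum spanning
tree over the exemplars is the seed. For embeddings with many components a
two-stage scheme fits the tree in the leading L components and lifts it to
the full dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AffinityPropagation, KMeans

__all__ = ["SeedGraph", "exemplar_cluster", "kruskal_mst", "seed_high_dim"]

#: cap on exemplar count to bound downstream grammar search
_MAX_EXEMPLARS = 50


@dataclass
class SeedGraph:
    node_coords: np.ndarray                 # nodes x d
    edges: list[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.node_coords.shape[0]
        assert np.all(np.isfinite(self.node_coords))
        assert len(self.edges) == n - 1, "seed graph must be a tree"
        assert _is_connected(n, self.edges), "seed graph must be connected"

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


def _is_connected(n: int, edges) -> bool:
    if n == 1:
        return True
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def exemplar_cluster(coords: np.ndarray, damping: float = 0.75,
                     random_seed: int = 0) -> np.ndarray:
    """Affinity-propagation exemplars of the embedded cells.

    Preference is left at the scikit-learn default (median similarity). If
    the message passing does not converge, falls back to k-means with
    k = round(sqrt(n)) and a fixed seed. Exemplar count is capped at 50 to
    bound the grammar search of the downstream tree growth.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("tree seeding needs at least 3 cells")
    if not (0.5 <= damping < 1):
        raise ValueError("damping must be in [0.5, 1)")
    if np.allclose(coords, coords[0]):
        return coords[:1].copy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ap = AffinityPropagation(damping=damping, random_state=0,
                                 max_iter=300).fit(coords)
        converged = not any("did not converge" in str(w.message).lower()
                            for w in caught)
    exemplars = ap.cluster_centers_ if converged else None
    if exemplars is None or len(exemplars) == 0:
        k = max(3, int(round(np.sqrt(n))))
        warnings.warn("affinity propagation did not converge; "
                      f"falling back to k-means with k={k}")
        km = KMeans(n_clusters=min(k, n), n_init=10,
                    random_state=random_seed).fit(coords)
        exemplars = km.cluster_centers_
    if len(exemplars) > _MAX_EXEMPLARS:
        km = KMeans(n_clusters=_MAX_EXEMPLARS, n_init=10,
                    random_state=random_seed).fit(coords)
        exemplars = km.cluster_centers_
    return np.asarray(exemplars, float)


def kruskal_mst(points: np.ndarray) -> SeedGraph:
    """Euclidean minimum spanning tree by Kruskal's algorithm.

    Edges of equal weight are broken by the lexicographic order of their
    node-id pair, making the tree deterministic under point relabeling
    only up to weight ties.
    """
    points = np.asarray(points, float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("MST needs at least 2 points")
    D = cdist(points, points)
    cand = sorted(
        ((D[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int]] = []
    for _, i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return SeedGraph(node_coords=points.copy(), edges=edges,
                     provenance={"method": "kruskal_mst"})


def seed_tree(emb_coords: np.ndarray, damping: float = 0.75,
              random_seed: int = 0) -> SeedGraph:
    """Exemplar clustering followed by Kruskal MST (the standard seeding)."""
    ex = exemplar_cluster(emb_coords, damping=damping,
                          random_seed=random_seed)
    if ex.shape[0] == 1:
        return SeedGraph(node_coords=ex, edges=[],
                         provenance={"method": "degenerate-single-exemplar"})
    g = kruskal_mst(ex)
    g.provenance.update(damping=damping, stage="low-dim",
                        n_exemplars=ex.shape[0])
    return g


def seed_high_dim(emb_coords: np.ndarray, L: int, k_lift: int = 5,
                  damping: float = 0.75, random_seed: int = 0,
                  fit_low_dim=None) -> SeedGraph:
    """Two-stage seeding: fit in the top L components, lift to full dimension.

    A tree is learnt on the leading L coordinates (``fit_low_dim``, by
    default seed+MST only; the pipeline passes a callable that also runs
    the elastic-graph fit). Node coordinates are lifted to H dimensions:
    the first L coordinates are copied, the remaining H-L set to the mean
    of the node's assigned cells; nodes with no assigned cells are imputed
    from their k_lift nearest cells. Edges are preserved.
    """
    emb_coords = np.asarray(emb_coords, float)
    H = emb_coords.shape[1]
    if L >= H:
        raise ValueError(f"L={L} must be below the embedding dimension {H}")
    low = emb_coords[:, :L]
    if fit_low_dim is None:
        g_low = seed_tree(low, damping=damping, random_seed=random_seed)
        low_nodes, low_edges = g_low.node_coords, g_low.edges
    else:
        low_nodes, low_edges = fit_low_dim(low)
    n_nodes = low_nodes.shape[0]

    assign = np.argmin(cdist(low, low_nodes), axis=1)
    lifted = np.zeros((n_nodes, H))
    lifted[:, :L] = low_nodes
    for j in range(n_nodes):
        cells = np.flatnonzero(assign == j)
        if cells.size:
            lifted[j, L:] = emb_coords[cells][:, L:].mean(axis=0)
        else:
            d_cells = np.linalg.norm(low - low_nodes[j], axis=1)
            nearest = np.argsort(d_cells)[:k_lift]
            lifted[j, L:] = emb_coords[nearest][:, L:].mean(axis=0)
    return SeedGraph(node_coords=lifted, edges=list(low_edges),
                     provenance={"method": "two-stage", "stage": "lifted",
                                 "L": L, "k_lift": k_lift})
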