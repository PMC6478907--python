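"""Post-growth refinements of the principal tree.

Four grammar-style rules cure artifacts of the global elastic fit:

* ``prune_branches`` removes leaf branches supported by too few cells or
  shorter than a minimal length — spurious branching events;
* ``shift_branching_nodes`` moves each branching node (degree >= 3) to the
  nearby region of highest cell density, where the true fate decision is
  biologically plausible;
* ``finetune_branching`` adds a few nodes around each branching node and
  re-optimizes only that star, resolving the local geometry;
* ``extend_leaves`` appends a node beyond each leaf so terminal cells are
  not piled onto a single node with identical pseudotime.

Every rule preserves tree-ness and leaves the rest of the geometry
untouched; they are applied in the order prune, shift, finetune, extend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .epg import ElasticParams, PrincipalGraph, optimize_nodes, _partition
from .tree_coords import extract_branches

__all__ = ["RefineParams", "prune_branches", "shift_branching_nodes",
           "finetune_branching", "extend_leaves", "refine_tree"]


@dataclass
class RefineParams:
    min_branch_cells: int = 5
    min_branch_length: float | None = None      # absolute override
    min_branch_length_frac: float = 0.05        # fraction of total tree length
    shift_radius: float | None = None           # None -> mean edge length
    finetune_n_nodes: int = 2
    extend_percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.min_branch_cells <= 0 or self.min_branch_length_frac <= 0:
            raise ValueError("prune thresholds must be positive")
        if self.finetune_n_nodes < 0:
            raise ValueError("finetune_n_nodes must be >= 0")
        if not (0 < self.extend_percentile <= 100):
            raise ValueError("extend_percentile in (0, 100]")


def _relabel(g: PrincipalGraph, keep: list[int]) -> PrincipalGraph:
    remap = {old: new for new, old in enumerate(keep)}
    edges = [(remap[u], remap[v]) for u, v in g.edges
             if u in remap and v in remap]
    return PrincipalGraph(node_coords=g.node_coords[keep], edges=edges,
                          energy_trace=list(g.energy_trace))


def _total_length(g: PrincipalGraph) -> float:
    return sum(float(np.linalg.norm(g.node_coords[u] - g.node_coords[v]))
               for u, v in g.edges)


def prune_branches(g: PrincipalGraph, X: np.ndarray,
                   rp: RefineParams) -> PrincipalGraph:
    """Iteratively remove undersupported or too-short leaf branches."""
    X = np.asarray(X, float)
    g = g.copy()
    while True:
        if g.n_nodes < 3:
            return g
        bs = extract_branches(g)
        if not bs.branches:
            return g
        min_len = (rp.min_branch_length if rp.min_branch_length is not None
                   else rp.min_branch_length_frac * _total_length(g))
        part, _ = _partition(X, g.node_coords)
        deg_states = bs.state_degrees()
        removable = None
        for bid in sorted(bs.branches):
            b = bs.branches[bid]
            d0, d1 = deg_states[b.states[0]], deg_states[b.states[1]]
            if d0 != 1 and d1 != 1:
                continue                      # internal branch
            if d0 == 1 and d1 == 1:
                continue                      # whole tree is one branch
            # nodes owned exclusively by this branch (leaf side)
            junction = b.node_path[0] if d0 != 1 else b.node_path[-1]
            owned = [v for v in b.node_path if v != junction]
            n_cells = int(np.isin(part, owned).sum())
            if n_cells < rp.min_branch_cells or b.length < min_len:
                removable = owned
                break
        if removable is None:
            return g
        keep = [v for v in range(g.n_nodes) if v not in set(removable)]
        if len(keep) < 2:
            warnings.warn("pruning would leave fewer than 2 nodes; skipped")
            return g
        g = _relabel(g, keep)
        g.partition, _ = _partition(X, g.node_coords)


def shift_branching_nodes(g: PrincipalGraph, X: np.ndarray,
                          rp: RefineParams) -> PrincipalGraph:
    """Move each branching node to the nearby cell-density mode.

    Among the cells within ``shift_radius`` of the node, the cell position
    maximizing a Gaussian kernel density estimate (bandwidth radius/2) is
    the new node position; degree-2 nodes never move.
    """
    X = np.asarray(X, float)
    g = g.copy()
    deg = g.degrees()
    radius = rp.shift_radius
    if radius is None:
        lengths = [np.linalg.norm(g.node_coords[u] - g.node_coords[v])
                   for u, v in g.edges]
        radius = float(np.mean(lengths)) if lengths else 1.0
    for v in np.flatnonzero(deg >= 3):
        d = np.linalg.norm(X - g.node_coords[v], axis=1)
        local = np.flatnonzero(d <= radius)
        if local.size == 0:
            warnings.warn(f"no cells within radius of branching node {v}; "
                          "left unmoved")
            continue
        pts = X[local]
        bw = radius / 2.0
        pair = cdist(pts, pts) ** 2
        dens = np.exp(-pair / (2 * bw ** 2)).sum(axis=1)
        g.node_coords[v] = pts[int(np.argmax(dens))]
    g.partition, _ = _partition(X, g.node_coords)
    return g


def _mean_projection_dist(g: PrincipalGraph, X: np.ndarray) -> float:
    best = np.full(X.shape[0], np.inf)
    for u, v in g.edges:
        a, b = g.node_coords[u], g.node_coords[v]
        seg = b - a
        L2 = float(seg @ seg)
        t = np.clip((X - a) @ seg / max(L2, 1e-12), 0.0, 1.0)
        d = np.linalg.norm(X - (a + t[:, None] * seg), axis=1)
        best = np.minimum(best, d)
    return float(best.mean())


def finetune_branching(g: PrincipalGraph, X: np.ndarray, rp: RefineParams,
                       p: ElasticParams | None = None) -> PrincipalGraph:
    """Insert nodes on edges around each branching node, re-optimize the star.

    The local splitting optimization of the star is accepted only when it
    does not worsen the mean orthogonal cell-to-tree distance; otherwise
    the plain midpoint insertion (which leaves geometry unchanged) is
    kept. This guards against the elastic penalties over-smoothing the
    very region the extra nodes are meant to resolve.
    """
    X = np.asarray(X, float)
    g = g.copy()
    if rp.finetune_n_nodes == 0:
        return g
    if p is None:
        p = ElasticParams()
    branching = [int(v) for v in np.flatnonzero(g.degrees() >= 3)]
    for center in branching:
        adj = g.neighbors()
        incident = sorted(adj[center])
        local = {center, *incident}
        # cycle over incident edges, bisecting until n extra nodes added
        for i in range(rp.finetune_n_nodes):
            adj = g.neighbors()
            incident = sorted(adj[center])
            nb = incident[i % len(incident)]
            mid = 0.5 * (g.node_coords[center] + g.node_coords[nb])
            new_id = g.n_nodes
            g.edges.remove((center, nb) if (center, nb) in g.edges
                           else (nb, center))
            g.edges += [(center, new_id), (new_id, nb)]
            g.node_coords = np.vstack([g.node_coords, mid])
            local.add(new_id)
        free = np.zeros(g.n_nodes, dtype=bool)
        free[list(local)] = True
        before = _mean_projection_dist(g, X)
        tuned = optimize_nodes(X, g, p, max_iter=20, free=free)
        if _mean_projection_dist(tuned, X) <= before + 1e-12:
            g = tuned
    g.partition, _ = _partition(X, g.node_coords)
    return g


def extend_leaves(g: PrincipalGraph, X: np.ndarray,
                  rp: RefineParams) -> PrincipalGraph:
    """Append a node beyond each leaf covering the tail of its point cloud.

    The new node lies on the ray from the leaf's neighbor through the
    leaf, at the ``extend_percentile`` of the assigned cells' projections
    beyond the leaf; leaves with no cells beyond them are left alone.
    """
    X = np.asarray(X, float)
    g = g.copy()
    part, _ = _partition(X, g.node_coords)
    deg = g.degrees()
    adj = g.neighbors()
    for leaf in np.flatnonzero(deg == 1):
        nb = adj[leaf][0]
        direction = g.node_coords[leaf] - g.node_coords[nb]
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        direction = direction / norm
        cells = np.flatnonzero(part == leaf)
        if cells.size == 0:
            continue
        t = (X[cells] - g.node_coords[leaf]) @ direction
        beyond = t[t > 0]
        if beyond.size == 0:
            continue
        reach = float(np.percentile(beyond, rp.extend_percentile))
        if reach <= 0:
            continue
        new_id = g.n_nodes
        g.node_coords = np.vstack(
            [g.node_coords, g.node_coords[leaf] + reach * direction])
        g.edges.append((int(leaf), new_id))
    g.partition, _ = _partition(X, g.node_coords)
    return g


def refine_tree(g: PrincipalGraph, X: np.ndarray, rp: RefineParams,
                p: ElasticParams | None = None) -> PrincipalGraph:
    """Apply prune -> shift -> finetune -> extend in order."""
    g = prune_branches(g, X, rp)
    if np.any(g.degrees() >= 3):
        g = shift_branching_nodes(g, X, rp)
        g = finetune_branching(g, X, rp, p)
    g = extend_leaves(g, X, rp)
    assert g.is_tree()
    return g
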