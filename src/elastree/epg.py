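"""Elastic principal tree: energy, node optimization, grammar-based growth.

A principal tree is a set of nodes embedded in the data space and connected
by edges, minimizing a sum of three terms:

* the (trimmed) mean squared distance of each data point to its nearest
  node — points farther than the trimming radius R0 contribute R0^2;
* an edge-stretching penalty: for each edge, the squared edge length
  weighted by ``lambda + alpha * (max(2, deg(u), deg(v)) - 2)``, so that
  alpha explicitly taxes edges incident to branching nodes and thereby
  controls the propensity to branch;
* a star-bending penalty: for each node of degree >= 2, mu times the
  squared deviation of the node from the mean of its neighbors (a star
  whose center sits at its neighbors' mean is "harmonic" and costs 0).

Given a partition of points to nodes, the energy is quadratic in node
coordinates and is minimized exactly by a linear solve; alternating the
partition and the solve (a splitting-type algorithm) decreases the energy
monotonically. Tree topology is grown with graph-grammar moves (add a node
to a node, bisect an edge): at each step every applicable move is tried,
each candidate is partially optimized, and the minimum-energy candidate is
accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .seeding import SeedGraph, _is_connected

__all__ = ["ElasticParams", "PrincipalGraph", "elastic_energy",
           "optimize_nodes", "grow_tree"]


@dataclass
class ElasticParams:
    """Elastic moduli and growth target of the principal tree."""

    R0: float = np.inf            # trimming radius
    lam: float = 0.02             # edge-stretching modulus
    mu: float = 0.1               # star-bending modulus
    alpha: float = 0.02           # branching-control coefficient, (0, 1]
    n_nodes_target: int | None = None   # None -> min(30, round(n_cells/10))

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.mu <= 0:
            raise ValueError("lambda and mu must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive or infinite")


@dataclass
class PrincipalGraph:
    """Tree nodes embedded in the data space, with per-point partition."""

    node_coords: np.ndarray                    # nodes x d
    edges: list[tuple[int, int]]
    partition: np.ndarray | None = None        # cell -> nearest node index
    energy_trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def is_tree(self) -> bool:
        return (len(self.edges) == self.n_nodes - 1
                and _is_connected(self.n_nodes, self.edges))

    def copy(self) -> "PrincipalGraph":
        return PrincipalGraph(
            node_coords=self.node_coords.copy(),
            edges=list(self.edges),
            partition=None if self.partition is None else self.partition.copy(),
            energy_trace=list(self.energy_trace),
        )


def _partition(X: np.ndarray, nodes: np.ndarray):
    D = cdist(X, nodes)
    p = np.argmin(D, axis=1)
    d = D[np.arange(X.shape[0]), p]
    return p, d


def _edge_weights(g: PrincipalGraph, p: ElasticParams) -> np.ndarray:
    deg = g.degrees()
    w = np.empty(len(g.edges))
    for i, (u, v) in enumerate(g.edges):
        w[i] = p.lam + p.alpha * (max(2, deg[u], deg[v]) - 2)
    return w


def elastic_energy(X: np.ndarray, g: PrincipalGraph, p: ElasticParams):
    """Total elastic energy and its (data, edge, star) components."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    X = np.asarray(X, float)
    part, dists = _partition(X, g.node_coords)
    sq = dists ** 2
    if np.isfinite(p.R0):
        sq = np.minimum(sq, p.R0 ** 2)
    mse_term = float(sq.mean())

    w = _edge_weights(g, p)
    edge_term = 0.0
    for wi, (u, v) in zip(w, g.edges):
        edge_term += wi * float(
            np.sum((g.node_coords[u] - g.node_coords[v]) ** 2))

    star_term = 0.0
    adj = g.neighbors()
    for c in range(g.n_nodes):
        if len(adj[c]) >= 2:
            center = g.node_coords[c]
            leaf_mean = g.node_coords[adj[c]].mean(axis=0)
            star_term += float(np.sum((center - leaf_mean) ** 2))
    star_term *= p.mu
    return mse_term + edge_term + star_term, mse_term, edge_term, star_term


def _solve_node_positions(X, g: PrincipalGraph, p: ElasticParams,
                          part, inside, free=None):
    """Exact minimizer of the energy in node coordinates, fixed partition.

    ``free``: optional boolean mask; only those nodes move (used by the
    local branching finetuning), others are held fixed.
    """
    n_nodes, d = g.n_nodes, g.node_coords.shape[1]
    N = X.shape[0]
    A = np.zeros((n_nodes, n_nodes))
    B = np.zeros((n_nodes, d))
    counts = np.bincount(part[inside], minlength=n_nodes)
    A[np.diag_indices(n_nodes)] += counts / N
    np.add.at(B, part[inside], X[inside] / N)

    w = _edge_weights(g, p)
    for wi, (u, v) in zip(w, g.edges):
        A[u, u] += wi
        A[v, v] += wi
        A[u, v] -= wi
        A[v, u] -= wi

    adj = g.neighbors()
    for c in range(n_nodes):
        k = len(adj[c])
        if k >= 2:
            a = np.zeros(n_nodes)
            a[c] = 1.0
            a[adj[c]] -= 1.0 / k
            A += p.mu * np.outer(a, a)

    if free is not None and not np.all(free):
        fixed = ~free
        Bf = B[free] - A[np.ix_(free, fixed)] @ g.node_coords[fixed]
        Af = A[np.ix_(free, free)]
        coords = g.node_coords.copy()
        coords[free] = _safe_solve(Af, Bf, g.node_coords[free])
        return coords
    return _safe_solve(A, B, g.node_coords)


def _safe_solve(A, B, fallback):
    try:
        cond = np.linalg.cond(A)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular node system; ridge-regularized solve")
        A = A + 1e-9 * np.eye(A.shape[0])
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        return fallback


def optimize_nodes(X: np.ndarray, g: PrincipalGraph, p: ElasticParams,
                   max_iter: int = 50, tol: float = 1e-6,
                   free=None) -> PrincipalGraph:
    """Splitting-type optimization: alternate partition and exact solve.

    The energy never increases across iterations (each half-step is an
    exact minimization of the same objective).
    """
    X = np.asarray(X, float)
    g = g.copy()
    prev = None
    for _ in range(max_iter):
        part, dists = _partition(X, g.node_coords)
        inside = (dists <= p.R0) if np.isfinite(p.R0) else np.ones(
            len(dists), dtype=bool)
        if np.isfinite(p.R0) and not inside.any():
            warnings.warn("trimming radius excludes every point; "
                          "node positions left unchanged")
            g.partition = part
            return g
        g.node_coords = _solve_node_positions(X, g, p, part, inside,
                                              free=free)
        U, *_ = elastic_energy(X, g, p)
        if prev is not None and abs(prev - U) <= tol * max(abs(prev), 1.0):
            break
        prev = U
    g.partition, _ = _partition(X, g.node_coords)
    return g


def _grammar_candidates(g: PrincipalGraph, X: np.ndarray):
    """Deterministic enumeration of add-node-to-node and bisect-edge moves."""
    cands = []
    part, _ = _partition(X, g.node_coords)
    adj = g.neighbors()
    centroid = X.mean(axis=0)
    for v in range(g.n_nodes):
        cells = np.flatnonzero(part == v)
        if cells.size:
            new_pos = X[cells].mean(axis=0)
        elif adj[v]:
            new_pos = 2 * g.node_coords[v] - g.node_coords[adj[v]].mean(axis=0)
        else:
            new_pos = centroid
        if np.allclose(new_pos, g.node_coords[v]):
            # degenerate extrapolation: nudge toward data centroid
            direction = centroid - g.node_coords[v]
            if np.linalg.norm(direction) < 1e-12:
                direction = np.ones_like(direction)
            new_pos = g.node_coords[v] + 1e-3 * direction
        cand = PrincipalGraph(
            node_coords=np.vstack([g.node_coords, new_pos]),
            edges=g.edges + [(v, g.n_nodes)],
        )
        cands.append(("add_node", v, cand))
    for ei, (u, v) in enumerate(g.edges):
        mid = 0.5 * (g.node_coords[u] + g.node_coords[v])
        new_id = g.n_nodes
        edges = [e for e in g.edges if e != (u, v)]
        edges += [(u, new_id), (new_id, v)]
        cand = PrincipalGraph(
            node_coords=np.vstack([g.node_coords, mid]), edges=edges)
        cands.append(("bisect_edge", ei, cand))
    return cands


def grow_tree(X: np.ndarray, seed: SeedGraph | PrincipalGraph,
              p: ElasticParams, candidate_iter: int = 10,
              collect_candidate_energies: bool = False) -> PrincipalGraph:
    """Grow a principal tree from a seed by energy-minimizing grammar moves.

    Every applicable move is applied at every site, each candidate is
    optimized for ``candidate_iter`` splitting iterations, and the
    candidate with minimal energy is accepted (ties broken by enumeration
    order) and fully converged. Growth stops at ``n_nodes_target``.
    """
    X = np.asarray(X, float)
    if isinstance(seed, SeedGraph):
        g = PrincipalGraph(node_coords=seed.node_coords.copy(),
                           edges=list(seed.edges))
    else:
        g = seed.copy()
    if not g.is_tree():
        raise ValueError("seed must be a tree")
    target = p.n_nodes_target
    if target is None:
        target = min(30, max(2, int(round(X.shape[0] / 10))))
    g = optimize_nodes(X, g, p)
    U, *_ = elastic_energy(X, g, p)
    trace: list = [(g.n_nodes, U)]
    g.energy_trace = trace
    if target < g.n_nodes:
        warnings.warn("n_nodes_target below seed size; returning optimized "
                      "seed unchanged")
        return g

    while g.n_nodes < target:
        best = None
        best_energy = np.inf
        energies = []
        for _, _, cand in _grammar_candidates(g, X):
            cand = optimize_nodes(X, cand, p, max_iter=candidate_iter)
            Uc, *_ = elastic_energy(X, cand, p)
            energies.append(Uc)
            if Uc < best_energy:       # strict: earliest candidate wins ties
                best_energy = Uc
                best = cand
        assert best is not None and best_energy <= min(energies) + 1e-12
        g = optimize_nodes(X, best, p)
        U, *_ = elastic_energy(X, g, p)
        if collect_candidate_energies:
            trace.append((g.n_nodes, U, tuple(energies)))
        else:
            trace.append((g.n_nodes, U))
        g.energy_trace = trace
    return g
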