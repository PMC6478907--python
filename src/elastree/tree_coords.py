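"""Branch extraction, cell projection, pseudotime, and 2D tree layouts.

States (nodes of degree != 2) are named S0, S1, ... in node-id order;
branches are the maximal degree-2 paths between states, identified by
their endpoint state pair ("S0-S1"). Cells are projected orthogonally onto
the nearest edge segment; pseudotime is the geodesic distance along the
tree from a chosen root state to the projection point.

The flat-tree layout places states in the plane with a seeded force-based
initialization refined by stress majorization on tree geodesic distances,
so drawn branch lengths track the embedding branch lengths. The subway
layout roots the tree at a state and uses pseudotime as x with branches
stacked in breadth-first lanes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize

__all__ = ["Branch", "BranchSet", "CellProjection", "TreeLayout",
           "extract_branches", "project_cells", "pseudotime",
           "flat_tree_layout", "subway_layout"]


@dataclass
class Branch:
    branch_id: str                  # "S0-S1"
    states: tuple[str, str]
    node_path: list[int]            # ordered node ids, state to state
    length: float                   # sum of consecutive node distances
    seg_lengths: np.ndarray         # per-segment lengths along the path


@dataclass
class BranchSet:
    branches: dict[str, Branch]
    state_nodes: dict[str, int]     # state name -> node id
    node_states: dict[int, str]

    def leaf_branches(self, degrees: dict[str, int]) -> list[str]:
        return [bid for bid, b in self.branches.items()
                if degrees[b.states[0]] == 1 or degrees[b.states[1]] == 1]

    def state_degrees(self) -> dict[str, int]:
        deg = {s: 0 for s in self.state_nodes}
        for b in self.branches.values():
            deg[b.states[0]] += 1
            deg[b.states[1]] += 1
        return deg


@dataclass
class CellProjection:
    branch_id: str
    position: float                 # arc-length offset from branch start
    dist: float                     # orthogonal distance to the branch
    side: int                       # +/-1 lateral placement for plotting


@dataclass
class TreeLayout:
    node_coords: dict[int, np.ndarray]      # graph node -> 2D position
    cell_coords: np.ndarray                 # cells x 2
    root_state: str | None
    cell_pseudotime: np.ndarray | None
    branch_segments: dict[str, tuple[np.ndarray, np.ndarray]]  # endpoints


def extract_branches(g) -> BranchSet:
    """Maximal degree-!=2 paths of the principal tree, named by states."""
    deg = g.degrees()
    adj = g.neighbors()
    if g.n_nodes == 1:
        s = {"S0": 0}
        return BranchSet(branches={}, state_nodes=s, node_states={0: "S0"})
    state_ids = [v for v in range(g.n_nodes) if deg[v] != 2]
    if not state_ids:
        raise ValueError("graph has no state nodes (is it a cycle?)")
    node_states = {v: f"S{i}" for i, v in enumerate(state_ids)}
    state_nodes = {s: v for v, s in node_states.items()}

    branches: dict[str, Branch] = {}
    visited_edges: set[frozenset] = set()
    for v in state_ids:
        for nb in adj[v]:
            if frozenset((v, nb)) in visited_edges:
                continue
            path = [v, nb]
            visited_edges.add(frozenset((v, nb)))
            while deg[path[-1]] == 2:
                nxt = [w for w in adj[path[-1]] if w != path[-2]][0]
                visited_edges.add(frozenset((path[-1], nxt)))
                path.append(nxt)
            a, b = node_states[path[0]], node_states[path[-1]]
            if int(a[1:]) > int(b[1:]):
                a, b = b, a
                path = path[::-1]
            seg = np.array([
                float(np.linalg.norm(g.node_coords[path[i + 1]]
                                     - g.node_coords[path[i]]))
                for i in range(len(path) - 1)
            ])
            bid = f"{a}-{b}"
            branches[bid] = Branch(branch_id=bid, states=(a, b),
                                   node_path=path,
                                   length=float(seg.sum()),
                                   seg_lengths=seg)
    return BranchSet(branches=branches, state_nodes=state_nodes,
                     node_states=node_states)


def project_cells(g, X: np.ndarray, branch_set: BranchSet | None = None,
                  random_seed: int = 0) -> list[CellProjection]:
    """Project each cell onto its nearest point on any edge segment.

    Ties between equidistant branches go to the lexicographically first
    branch id. The plotting side (+/-1) is drawn pseudo-randomly from the
    run seed.
    """
    X = np.asarray(X, float)
    if branch_set is None:
        branch_set = extract_branches(g)
    n = X.shape[0]
    best_dist = np.full(n, np.inf)
    best_bid = np.empty(n, dtype=object)
    best_pos = np.zeros(n)
    for bid in sorted(branch_set.branches):
        b = branch_set.branches[bid]
        offset = 0.0
        for i in range(len(b.node_path) - 1):
            a = g.node_coords[b.node_path[i]]
            c = g.node_coords[b.node_path[i + 1]]
            seg = c - a
            L2 = float(seg @ seg)
            if L2 == 0:
                t = np.zeros(n)
            else:
                t = np.clip((X - a) @ seg / L2, 0.0, 1.0)
            proj = a + t[:, None] * seg
            d = np.linalg.norm(X - proj, axis=1)
            better = d < best_dist - 1e-15
            best_dist[better] = d[better]
            best_bid[better] = bid
            best_pos[better] = offset + t[better] * np.sqrt(L2)
            offset += np.sqrt(L2)
    rng = np.random.default_rng(random_seed)
    sides = rng.choice([-1, 1], size=n)
    return [CellProjection(branch_id=str(best_bid[i]),
                           position=float(best_pos[i]),
                           dist=float(best_dist[i]), side=int(sides[i]))
            for i in range(n)]


def _state_graph(branch_set: BranchSet) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(branch_set.state_nodes)
    for b in branch_set.branches.values():
        # multigraph-free: a tree never has two branches between same states
        G.add_edge(b.states[0], b.states[1], length=b.length,
                   branch_id=b.branch_id)
    return G


def pseudotime(g, projections: list[CellProjection], root_state: str,
               branch_set: BranchSet | None = None) -> np.ndarray:
    """Geodesic distance from the root state to each cell's projection point."""
    if branch_set is None:
        branch_set = extract_branches(g)
    if root_state not in branch_set.state_nodes:
        raise ValueError(
            f"unknown root {root_state!r}; valid states: "
            f"{sorted(branch_set.state_nodes)}"
        )
    G = _state_graph(branch_set)
    dist = nx.single_source_dijkstra_path_length(G, root_state,
                                                 weight="length")
    pt = np.empty(len(projections))
    for i, pr in enumerate(projections):
        b = branch_set.branches[pr.branch_id]
        du = dist[b.states[0]] + pr.position
        dv = dist[b.states[1]] + (b.length - pr.position)
        pt[i] = min(du, dv)
    return pt


def node_pseudotime(g, root_state: str,
                    branch_set: BranchSet | None = None) -> dict[int, float]:
    """Geodesic distance from the root state to every graph node."""
    if branch_set is None:
        branch_set = extract_branches(g)
    root_node = branch_set.state_nodes[root_state]
    G = nx.Graph()
    for u, v in g.edges:
        G.add_edge(u, v, length=float(
            np.linalg.norm(g.node_coords[u] - g.node_coords[v])))
    return nx.single_source_dijkstra_path_length(G, root_node,
                                                  weight="length")


def default_root(branch_set: BranchSet, cell_labels=None,
                 projections=None) -> str:
    """Leaf state at the end of the longest path (no label heuristics)."""
    G = _state_graph(branch_set)
    deg = branch_set.state_degrees()
    leaves = sorted(s for s, d in deg.items() if d <= 1)
    if not leaves:
        return "S0"
    best, best_len = leaves[0], -1.0
    for s in leaves:
        far = max(nx.single_source_dijkstra_path_length(
            G, s, weight="length").values())
        if far > best_len:
            best, best_len = s, far
    return best


def _stress(flat_pos, states, targets, weights):
    pos = flat_pos.reshape(len(states), 2)
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2) + 1e-12)
    err = d - targets
    val = float((weights * err ** 2).sum())
    grad = (2 * weights * err / d)[:, :, None] * diff
    return val, grad.sum(axis=1).ravel()


def flat_tree_layout(g, projections=None, branch_set=None,
                     random_seed: int = 0) -> TreeLayout:
    """2D length-preserving layout of the tree, cells beside their branch.

    States get seeded random initial positions; stress majorization on the
    geodesic state-to-state distances (adjacent pairs up-weighted) pulls
    drawn branch lengths to the embedding branch lengths. Interior branch
    nodes are placed proportionally along the straight state-to-state
    segment; each cell sits at its arc-length offset, displaced laterally
    by its orthogonal distance times its side.
    """
    if branch_set is None:
        branch_set = extract_branches(g)
    states = sorted(branch_set.state_nodes)
    G = _state_graph(branch_set)
    if len(states) == 1:
        node_coords = {branch_set.state_nodes[states[0]]: np.zeros(2)}
        return TreeLayout(node_coords=node_coords,
                          cell_coords=np.zeros((0, 2)), root_state=None,
                          cell_pseudotime=None, branch_segments={})
    targets = np.zeros((len(states), len(states)))
    for i, si in enumerate(states):
        dd = nx.single_source_dijkstra_path_length(G, si, weight="length")
        for j, sj in enumerate(states):
            targets[i, j] = dd[sj]
    weights = 1.0 / np.maximum(targets, 1e-9) ** 2
    np.fill_diagonal(weights, 0.0)
    for u, v in G.edges:
        i, j = states.index(u), states.index(v)
        weights[i, j] = weights[j, i] = weights[i, j] * 10.0  # edge fidelity

    rng = np.random.default_rng(random_seed)
    scale = targets.max() if targets.max() > 0 else 1.0
    x0 = rng.normal(scale=0.1 * scale, size=(len(states), 2)).ravel()
    res = minimize(_stress, x0, args=(states, targets, weights),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    pos = res.x.reshape(len(states), 2)
    state_pos = {s: pos[i] for i, s in enumerate(states)}

    node_coords: dict[int, np.ndarray] = {
        branch_set.state_nodes[s]: state_pos[s] for s in states}
    branch_segments = {}
    for bid, b in branch_set.branches.items():
        pa, pb = state_pos[b.states[0]], state_pos[b.states[1]]
        branch_segments[bid] = (pa, pb)
        cum = np.concatenate([[0.0], np.cumsum(b.seg_lengths)])
        for i, node in enumerate(b.node_path):
            frac = cum[i] / b.length if b.length > 0 else 0.0
            node_coords[node] = pa + frac * (pb - pa)

    cell_coords = np.zeros((0, 2))
    if projections is not None:
        cell_coords = np.zeros((len(projections), 2))
        for i, pr in enumerate(projections):
            b = branch_set.branches[pr.branch_id]
            pa, pb = branch_segments[pr.branch_id]
            u = (pb - pa)
            L = np.linalg.norm(u)
            u = u / L if L > 0 else np.array([1.0, 0.0])
            perp = np.array([-u[1], u[0]])
            frac = pr.position / b.length if b.length > 0 else 0.0
            cell_coords[i] = pa + frac * (pb - pa) + perp * pr.dist * pr.side
    return TreeLayout(node_coords=node_coords, cell_coords=cell_coords,
                      root_state=None, cell_pseudotime=None,
                      branch_segments=branch_segments)


def subway_layout(g, root_state: str, projections=None,
                  branch_set=None) -> TreeLayout:
    """Rooted layout: x = pseudotime, branches stacked in BFS lanes."""
    if branch_set is None:
        branch_set = extract_branches(g)
    if root_state not in branch_set.state_nodes:
        raise ValueError(
            f"unknown root {root_state!r}; valid states: "
            f"{sorted(branch_set.state_nodes)}"
        )
    G = _state_graph(branch_set)
    dist = nx.single_source_dijkstra_path_length(G, root_state,
                                                 weight="length")
    # orient each branch away from the root
    tree = nx.bfs_tree(G, root_state)
    # lanes: leaves in BFS discovery order get successive integers,
    # internal states the mean of their children
    lane: dict[str, float] = {}
    next_lane = [0.0]

    def assign(s: str) -> float:
        children = sorted(tree.successors(s))
        if not children:
            lane[s] = next_lane[0]
            next_lane[0] += 1.0
        else:
            lane[s] = float(np.mean([assign(c) for c in children]))
        return lane[s]

    assign(root_state)
    state_pos = {s: np.array([dist[s], lane[s]]) for s in dist}

    node_coords: dict[int, np.ndarray] = {}
    branch_segments = {}
    pt_nodes = node_pseudotime(g, root_state, branch_set)
    for bid, b in branch_set.branches.items():
        sa, sb = b.states
        if dist[sa] > dist[sb]:
            sa, sb = sb, sa       # sa is the root-side state
        y = lane[sb]
        branch_segments[bid] = (np.array([dist[sa], y]),
                                np.array([dist[sb], y]))
        for node in b.node_path:
            node_coords[node] = np.array([pt_nodes[node], y])
    for s, v in branch_set.state_nodes.items():
        node_coords[v] = state_pos[s]

    cell_coords = np.zeros((0, 2))
    cell_pt = None
    if projections is not None:
        cell_pt = pseudotime(g, projections, root_state, branch_set)
        lane_gap = 1.0
        max_d = max((pr.dist for pr in projections), default=1.0) or 1.0
        shrink = 0.4 * lane_gap / max_d
        cell_coords = np.zeros((len(projections), 2))
        for i, pr in enumerate(projections):
            b = branch_set.branches[pr.branch_id]
            sa, sb = b.states
            if dist[sa] > dist[sb]:
                sa, sb = sb, sa
            y = lane[sb]
            cell_coords[i] = [cell_pt[i], y + pr.dist * pr.side * shrink]
    return TreeLayout(node_coords=node_coords, cell_coords=cell_coords,
                      root_state=root_state, cell_pseudotime=cell_pt,
                      branch_segments=branch_segments)
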