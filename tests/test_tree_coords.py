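import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra

from elastree.epg import PrincipalGraph
from elastree.tree_coords import (extract_branches, flat_tree_layout,
                                  project_cells, pseudotime, subway_layout)


@pytest.fixture
def y_graph():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [2.0, -1.0],
                       [-1.0, 0.0]])
    edges = [(0, 1), (1, 2), (1, 3), (4, 0)]
    return PrincipalGraph(node_coords=coords, edges=edges)


def test_branches_partition_edges_and_lengths_add_up(y_graph):
    bs = extract_branches(y_graph)
    # states: all nodes except 0 (degree 2): node 1 (deg 3), leaves 2,3,4
    assert len(bs.state_nodes) == 4
    n_edges = sum(len(b.node_path) - 1 for b in bs.branches.values())
    assert n_edges == len(y_graph.edges)
    total = sum(b.length for b in bs.branches.values())
    edge_total = sum(np.linalg.norm(y_graph.node_coords[u]
                                    - y_graph.node_coords[v])
                     for u, v in y_graph.edges)
    np.testing.assert_allclose(total, edge_total)


def test_cell_on_node_has_zero_distance(y_graph):
    X = y_graph.node_coords[[1]]
    pr = project_cells(y_graph, X)[0]
    assert pr.dist < 1e-12


def test_tie_goes_to_lexicographically_first_branch(y_graph):
    # point equidistant from both upper and lower arms
    X = np.array([[1.8, 0.0]])
    pr = project_cells(y_graph, X)[0]
    bs = extract_branches(y_graph)
    candidates = sorted(b for b in bs.branches
                        if bs.branches[b].length > 0)
    assert pr.branch_id == min(
        b for b in candidates
        if _dist_to_branch(y_graph, bs.branches[b], X[0])
        < _dist_to_branch(y_graph, bs.branches[candidates[0]], X[0]) + 1e-9)


def _dist_to_branch(g, b, x):
    best = np.inf
    for i in range(len(b.node_path) - 1):
        a, c = g.node_coords[b.node_path[i]], g.node_coords[b.node_path[i + 1]]
        seg = c - a
        t = np.clip((x - a) @ seg / max(seg @ seg, 1e-12), 0, 1)
        best = min(best, np.linalg.norm(x - (a + t * seg)))
    return best


def test_projection_distance_bounded_by_nearest_node(y_graph):
    rng = np.random.default_rng(0)
    X = rng.uniform(-2, 3, size=(50, 2))
    prs = project_cells(y_graph, X)
    for x, pr in zip(X, prs):
        nearest_node = np.min(np.linalg.norm(
            y_graph.node_coords - x, axis=1))
        assert pr.dist <= nearest_node + 1e-12


def test_pseudotime_zero_at_root_and_additive(y_graph):
    bs = extract_branches(y_graph)
    root = bs.node_states[4]
    X = np.array([[-1.0, 0.0], [-0.5, 0.0], [-0.2, 0.0]])
    prs = project_cells(y_graph, X)
    pt = pseudotime(y_graph, prs, root)
    assert pt[0] < 1e-12
    np.testing.assert_allclose(pt[2] - pt[1], 0.3, atol=1e-9)


def test_pseudotime_matches_dijkstra_oracle(y_graph):
    rng = np.random.default_rng(1)
    X = rng.uniform(-1.5, 2.5, size=(40, 2))
    bs = extract_branches(y_graph)
    root_state = bs.node_states[4]
    prs = project_cells(y_graph, X)
    pt = pseudotime(y_graph, prs, root_state)
    # independent oracle: scipy dijkstra over the node graph + offset
    n = y_graph.n_nodes
    W = lil_matrix((n, n))
    for u, v in y_graph.edges:
        w = np.linalg.norm(y_graph.node_coords[u] - y_graph.node_coords[v])
        W[u, v] = W[v, u] = w
    dist = dijkstra(W.tocsr(), indices=4)
    for i, pr in enumerate(prs):
        b = bs.branches[pr.branch_id]
        u, v = b.node_path[0], b.node_path[-1]
        expect = min(dist[u] + pr.position,
                     dist[v] + b.length - pr.position)
        np.testing.assert_allclose(pt[i], expect, atol=1e-9)


def test_unknown_root_lists_valid_states(y_graph):
    prs = project_cells(y_graph, y_graph.node_coords[:2])
    with pytest.raises(ValueError, match="S0"):
        pseudotime(y_graph, prs, "S99")


def test_pseudotime_monotone_along_root_to_leaf_paths(y_graph):
    # sample points marching along the lower arm
    t = np.linspace(0, 1, 20)
    X = np.array([[1.0, 0.0]]) + t[:, None] * np.array([[1.0, -1.0]])
    bs = extract_branches(y_graph)
    prs = project_cells(y_graph, X)
    pt = pseudotime(y_graph, prs, bs.node_states[4])
    assert np.all(np.diff(pt) >= -1e-9)


def test_two_node_flat_layout_is_exact_segment():
    g = PrincipalGraph(node_coords=np.array([[0.0, 0.0], [3.0, 4.0]]),
                       edges=[(0, 1)])
    layout = flat_tree_layout(g)
    pts = list(layout.node_coords.values())
    drawn = np.linalg.norm(pts[0] - pts[1])
    np.testing.assert_allclose(drawn, 5.0, rtol=1e-3)


def test_flat_layout_preserves_branch_lengths(y_graph):
    for seed in (0, 1):
        layout = flat_tree_layout(y_graph, random_seed=seed)
        bs = extract_branches(y_graph)
        for bid, b in bs.branches.items():
            a, c = layout.branch_segments[bid]
            drawn = np.linalg.norm(a - c)
            assert abs(drawn - b.length) / b.length < 0.05
    # same seed -> identical layout
    l1 = flat_tree_layout(y_graph, random_seed=3)
    l2 = flat_tree_layout(y_graph, random_seed=3)
    for k in l1.node_coords:
        np.testing.assert_array_equal(l1.node_coords[k], l2.node_coords[k])


def test_subway_linear_tree_single_lane():
    g = PrincipalGraph(node_coords=np.array([[0.0, 0.0], [1.0, 0.0],
                                             [2.0, 0.0]]),
                       edges=[(0, 1), (1, 2)])
    bs = extract_branches(g)
    layout = subway_layout(g, "S0", branch_set=bs)
    ys = {tuple(np.round(v, 9))[1] for v in layout.node_coords.values()}
    assert len(ys) == 1
    xs = [v[0] for v in layout.node_coords.values()]
    np.testing.assert_allclose(max(xs), 2.0)


def test_subway_y_tree_two_lanes_from_branching_x(y_graph):
    bs = extract_branches(y_graph)
    root = bs.node_states[4]
    rng = np.random.default_rng(2)
    X = rng.uniform(-1, 2, size=(30, 2))
    prs = project_cells(y_graph, X)
    layout = subway_layout(y_graph, root, projections=prs, branch_set=bs)
    # the two child branches sit at distinct lanes
    child_ys = {np.round(layout.node_coords[2][1], 9),
                np.round(layout.node_coords[3][1], 9)}
    assert len(child_ys) == 2
    # x of every cell equals its pseudotime
    pt = pseudotime(y_graph, prs, root, bs)
    np.testing.assert_allclose(layout.cell_coords[:, 0], pt)
    assert np.isclose(layout.cell_coords[:, 0].max(), pt.max())
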