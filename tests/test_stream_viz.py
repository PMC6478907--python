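import numpy as np
import pytest

from elastree.epg import PrincipalGraph
from elastree.stream_viz import (render, smooth_and_assemble,
                                 window_densities, expression_cap)
from elastree.tree_coords import extract_branches, project_cells, pseudotime


@pytest.fixture
def line_tree():
    g = PrincipalGraph(node_coords=np.array([[0.0, 0.0], [1.0, 0.0],
                                             [2.0, 0.0]]),
                       edges=[(0, 1), (1, 2)])
    # evenly spaced cells: the analytic density is exactly uniform
    X = np.column_stack([np.linspace(0.0025, 1.9975, 400), np.zeros(400)])
    bs = extract_branches(g)
    prs = project_cells(g, X, bs)
    pt = pseudotime(g, prs, "S0", bs)
    return g, bs, prs, pt


@pytest.fixture
def y_stream(y_tree_result):
    m, truth, res = y_tree_result
    raw = window_densities(res.branch_set, res.projections,
                           res.pseudotime, labels=m.cell_labels,
                           root_state=res.root_state)
    return m, res, raw


def test_uniform_line_gives_flat_width(line_tree):
    g, bs, prs, pt = line_tree
    raw = window_densities(bs, prs, pt, root_state="S0")
    bw = raw[0]
    inner = bw.counts["all"][2:-2]
    assert np.all(np.abs(inner - inner.mean()) <= 0.1 * inner.mean())


def test_empty_branch_gets_zero_ribbon(y_tree_result):
    m, truth, res = y_tree_result
    # fake labels so that one label never occurs on some branch
    labels = ["X"] * m.n_cells
    raw = window_densities(res.branch_set, res.projections, res.pseudotime,
                           labels=labels, root_state=res.root_state)
    for bw in raw:
        assert set(bw.counts) == {"X"}
        assert np.all(bw.counts["X"] >= 0)


def test_width_conserved_through_bifurcation(y_tree_result):
    m, truth, res = y_tree_result
    raw = window_densities(res.branch_set, res.projections, res.pseudotime,
                           root_state=res.root_state)
    by_id = {bw.branch_id: bw for bw in raw}
    # find the parent branch (ends at the branching state) and children
    deg = res.branch_set.state_degrees()
    hub = [s for s, d in deg.items() if d >= 3][0]
    parent = [b for b in raw
              if hub in res.branch_set.branches[b.branch_id].states
              and b.t_start < min(
                  x.t_start for x in raw
                  if hub in res.branch_set.branches[x.branch_id].states) + 1e-9]
    parent = parent[0]
    children = [b for b in raw if b is not parent
                and hub in res.branch_set.branches[b.branch_id].states]
    assert len(children) == 2
    parent_w = parent.counts["all"][-1]
    child_w = sum(c.counts["all"][0] for c in children)
    assert abs(child_w - parent_w) <= 0.35 * parent_w


def test_savgol_preserves_constant_and_integral(line_tree):
    g, bs, prs, pt = line_tree
    raw = window_densities(bs, prs, pt, root_state="S0")
    geom = smooth_and_assemble(raw)
    bid = raw[0].branch_id
    total_raw = np.trapezoid(
        np.interp(geom.grids[bid], raw[0].centers, raw[0].counts["all"]),
        geom.grids[bid])
    total_smooth = np.trapezoid(geom.widths[bid]["all"], geom.grids[bid])
    assert abs(total_smooth - total_raw) <= 0.05 * total_raw


def test_stacked_label_widths_sum_to_branch_total(y_stream):
    m, res, raw = y_stream
    geom = smooth_and_assemble(raw)
    for bid in geom.grids:
        total = np.sum([geom.widths[bid][lab] for lab in geom.labels],
                       axis=0)
        # polygons stack exactly: top of last = base + total
        lower = geom.polygons[(bid, geom.labels[0])]
        n = geom.grids[bid].size
        base = lower[:n, 1]
        top = geom.polygons[(bid, geom.labels[-1])][n:, 1][::-1]
        np.testing.assert_allclose(top - base, total, atol=1e-10)


def test_equal_label_split_gives_equal_ribbons(line_tree):
    g, bs, prs, pt = line_tree
    labels = ["A", "B"] * 200
    raw = window_densities(bs, prs, pt, labels=labels, root_state="S0")
    geom = smooth_and_assemble(raw)
    bid = raw[0].branch_id
    wa, wb = geom.widths[bid]["A"], geom.widths[bid]["B"]
    inner = slice(3, -3)
    np.testing.assert_allclose(wa[inner], wb[inner],
                               atol=0.25 * wa[inner].mean())


def test_ribbon_extent_matches_branch_pseudotime_interval(y_stream):
    m, res, raw = y_stream
    geom = smooth_and_assemble(raw)
    for bw in raw:
        grid = geom.grids[bw.branch_id]
        assert np.isclose(grid[0], bw.t_start)
        assert np.isclose(grid[-1], bw.t_end)


def test_expression_cap_is_90th_percentile():
    vals = np.concatenate([np.ones(99), [1000.0]])
    assert expression_cap(vals) == np.percentile(vals, 90)


def test_render_views_and_svg_determinism(tmp_path, y_stream):
    m, res, raw = y_stream
    geom = smooth_and_assemble(raw)
    p1 = render("stream", tmp_path / "a.svg", geometry=geom,
                labels=m.cell_labels)
    p2 = render("stream", tmp_path / "b.svg", geometry=geom,
                labels=m.cell_labels)
    assert (tmp_path / "a.svg").read_bytes() == \
        (tmp_path / "b.svg").read_bytes()
    render("flat", tmp_path / "flat.png", tree=res.tree,
           branch_set=res.branch_set, projections=res.projections,
           labels=m.cell_labels)
    render("subway", tmp_path / "sub.png", tree=res.tree,
           branch_set=res.branch_set, projections=res.projections,
           root_state=res.root_state, color_by="gene", gene="g0000",
           expr=m.values, gene_names=m.feature_names)
    render("stream", tmp_path / "sg.png", geometry=geom,
           projections=res.projections, pt=res.pseudotime,
           color_by="gene", gene="g0000", expr=m.values,
           gene_names=m.feature_names)
    assert (tmp_path / "sg.png").exists()


def test_unknown_gene_suggests_nearest_name(tmp_path, y_stream):
    m, res, raw = y_stream
    with pytest.raises(KeyError, match="did you mean"):
        render("flat", tmp_path / "x.png", tree=res.tree,
               branch_set=res.branch_set, projections=res.projections,
               color_by="gene", gene="g000O", expr=m.values,
               gene_names=m.feature_names)
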