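"""Stream-plot geometry (density ribbons) and rendering of the tree views.

A stream plot shows, per branch, a ribbon whose x-extent is the branch's
pseudotime interval and whose width at any pseudotime is proportional to
the number of cells there, stratified by cell label. Widths come from a
sliding-window count (window = a fraction of the longest root-to-leaf
path, stride = half a window); windows overhanging a branch's start also
count parent-branch cells, split across the children proportionally to
their occupancy, so the total width is conserved through a branching
event. Raw counts are normalized by the longest-path length, linearly
interpolated onto a uniform grid and smoothed with a Savitzky-Golay
filter before polygon assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from .data_model import auto_label_colors
from .tree_coords import (BranchSet, _state_graph, flat_tree_layout,
                          subway_layout)

import networkx as nx

__all__ = ["StreamGeometry", "window_densities", "smooth_and_assemble",
           "render"]

#: colormap cap: values above this percentile saturate
_CMAP_PERCENTILE = 90


@dataclass
class BranchWindows:
    branch_id: str
    t_start: float                  # pseudotime at the root-side state
    t_end: float
    centers: np.ndarray
    counts: dict[str, np.ndarray]   # label -> normalized width per window


@dataclass
class StreamGeometry:
    grids: dict[str, np.ndarray]                    # branch -> x grid
    widths: dict[str, dict[str, np.ndarray]]        # branch -> label -> width
    offsets: dict[str, float]                       # branch y-centers
    polygons: dict[tuple[str, str], np.ndarray]     # (branch,label) -> Nx2
    window: float
    norm_const: float
    labels: list[str]


def _branch_intervals(branch_set: BranchSet, root_state: str):
    """Per-branch pseudotime interval and parent/children relations."""
    G = _state_graph(branch_set)
    dist = nx.single_source_dijkstra_path_length(G, root_state,
                                                 weight="length")
    info = {}
    for bid, b in branch_set.branches.items():
        sa, sb = b.states
        if dist[sa] > dist[sb]:
            sa, sb = sb, sa
        info[bid] = {"near": sa, "far": sb,
                     "t0": dist[sa], "t1": dist[sb]}
    children = {bid: sorted(o for o, oi in info.items()
                            if oi["near"] == info[bid]["far"])
                for bid in info}
    parent = {}
    for bid, ch in children.items():
        for c in ch:
            parent[c] = bid
    return info, children, parent


def window_densities(branch_set: BranchSet, projections, pt, labels=None,
                     root_state: str = "S0", window_frac: float = 0.1
                     ) -> list[BranchWindows]:
    """Sliding-window cell counts per branch and label, junction-aware.

    Window width is ``window_frac`` of the longest path from the root;
    stride is half a window. Counts are divided by the longest-path
    length. At a branch's start the window reaches into the parent
    branch; parent cells in that overhang are attributed to each child in
    proportion to the children's occupancy of their first window.
    """
    if not branch_set.branches:
        raise ValueError("empty tree")
    pt = np.asarray(pt, float)
    n = len(projections)
    if labels is None:
        labels = ["all"] * n
    labels = list(labels)
    label_names = sorted(set(labels))
    cell_branch = np.array([p.branch_id for p in projections])

    info, children, parent = _branch_intervals(branch_set, root_state)
    longest = max(i["t1"] for i in info.values())
    if longest <= 0:
        raise ValueError("degenerate tree with zero total length")
    w = window_frac * longest
    stride = w / 2.0

    out = []
    for bid in sorted(branch_set.branches):
        t0, t1 = info[bid]["t0"], info[bid]["t1"]
        centers = np.arange(t0, t1 + stride / 2, stride)
        on_b = cell_branch == bid
        # sibling occupancy shares for the junction overhang
        share = 1.0
        if bid in parent:
            sibs = children[parent[bid]]
            occ = {}
            for s in sibs:
                s0 = info[s]["t0"]
                occ[s] = int(((cell_branch == s) & (pt >= s0)
                              & (pt <= s0 + w)).sum())
            tot = sum(occ.values())
            share = occ[bid] / tot if tot > 0 else 1.0 / len(sibs)
        kids = children[bid]
        counts = {}
        for lab in label_names:
            is_lab = np.array([l == lab for l in labels])
            c = np.zeros(centers.size)
            for k, x in enumerate(centers):
                lo, hi = x - w / 2, x + w / 2
                c[k] = ((on_b & is_lab & (pt >= max(lo, t0))
                         & (pt <= min(hi, t1))).sum())
                if lo < t0 and bid in parent:
                    # overhang into the parent: matched share of its cells
                    pb = parent[bid]
                    on_p = cell_branch == pb
                    c[k] += share * ((on_p & is_lab & (pt >= lo)
                                      & (pt < t0)).sum())
                if hi > t1 and kids:
                    # overhang past the junction: all children continue
                    # the parent's flow, so they count in full
                    for kid in kids:
                        on_k = cell_branch == kid
                        c[k] += ((on_k & is_lab & (pt > t1)
                                  & (pt <= hi)).sum())
            counts[lab] = c / longest
        out.append(BranchWindows(branch_id=bid, t_start=t0, t_end=t1,
                                 centers=centers, counts=counts))
    return out


def smooth_and_assemble(raw: list[BranchWindows], grid_points: int = 50,
                        sg_window: int = 11, sg_order: int = 3,
                        gap_frac: float = 0.2) -> StreamGeometry:
    """Interpolate, Savitzky-Golay smooth, and assemble stacked polygons.

    Each branch's width curves are linearly interpolated onto a uniform
    grid and smoothed (window shrunk to the nearest valid odd size on
    short branches); negative values clip to zero. Branch lanes are
    offset vertically by a greedy subtree packing so ribbons never
    overlap; per-label polygons are stacked within each branch.
    """
    labels = sorted({lab for bw in raw for lab in bw.counts})
    grids, widths = {}, {}
    for bw in raw:
        grid = np.linspace(bw.t_start, bw.t_end, grid_points)
        sm = {}
        for lab in labels:
            y = bw.counts.get(lab, np.zeros(bw.centers.size))
            if bw.centers.size == 1:
                interp = np.full(grid.size, float(y[0]))
            else:
                interp = np.interp(grid, bw.centers, y)
            win = min(sg_window, grid.size if grid.size % 2 == 1
                      else grid.size - 1)
            if win > sg_order:
                interp = savgol_filter(interp, win, sg_order)
            sm[lab] = np.clip(interp, 0.0, None)
        grids[bw.branch_id] = grid
        widths[bw.branch_id] = sm

    totals = {bid: np.sum([widths[bid][lab] for lab in labels], axis=0)
              for bid in grids}
    heights = {bid: float(totals[bid].max()) for bid in grids}
    gap = gap_frac * max(heights.values()) if heights else 0.0
    # greedy lane packing: branches sorted by start then id, stacked
    offsets: dict[str, float] = {}
    y_cursor = 0.0
    for bw in sorted(raw, key=lambda b: (b.t_start, b.branch_id)):
        bid = bw.branch_id
        offsets[bid] = y_cursor + heights[bid] / 2
        y_cursor += heights[bid] + gap

    polygons = {}
    for bid in grids:
        grid = grids[bid]
        base = offsets[bid] - totals[bid] / 2
        cum = base.copy()
        for lab in labels:
            top = cum + widths[bid][lab]
            poly = np.vstack([
                np.column_stack([grid, cum]),
                np.column_stack([grid[::-1], top[::-1]]),
            ])
            polygons[(bid, lab)] = poly
            cum = top
    window = raw[0].centers[1] - raw[0].centers[0] if raw and \
        raw[0].centers.size > 1 else 1.0
    longest = max(bw.t_end for bw in raw)
    return StreamGeometry(grids=grids, widths=widths, offsets=offsets,
                          polygons=polygons, window=2 * window,
                          norm_const=longest, labels=labels)


def expression_cap(values) -> float:
    """Colormap maximum: the 90th percentile of the given values."""
    return float(np.percentile(np.asarray(values, float), _CMAP_PERCENTILE))


def _save(fig, path):
    path = str(path)
    plt.rcParams["svg.hashsalt"] = "elastree"
    meta = {"Date": None} if path.endswith(".svg") else {}
    fig.savefig(path, metadata=meta)
    plt.close(fig)
    return path


def render(view: str, path, *, tree=None, branch_set=None, projections=None,
           pt=None, labels=None, label_colors=None, root_state=None,
           geometry: StreamGeometry | None = None, expr=None,
           gene_names=None, color_by: str = "label", gene: str | None = None,
           random_seed: int = 0):
    """Render a flat-tree, subway or stream view to a PNG/SVG file.

    ``color_by="gene"`` colors cells (or ribbon segments) by the given
    gene's expression, saturating at the 90th percentile; unknown gene
    names raise with a nearest-name suggestion. With no labels the stream
    ribbon is a single gray band.
    """
    if color_by == "gene":
        if gene_names is None or expr is None:
            raise ValueError("gene coloring needs expr and gene_names")
        if gene not in gene_names:
            import difflib
            hint = difflib.get_close_matches(gene or "", gene_names, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise KeyError(f"unknown gene {gene!r}{suffix}")
        gvals = np.asarray(expr)[list(gene_names).index(gene)]

    fig, ax = plt.subplots(figsize=(6, 4))
    if view in ("flat", "subway"):
        layout = (flat_tree_layout(tree, projections, branch_set,
                                   random_seed=random_seed)
                  if view == "flat"
                  else subway_layout(tree, root_state, projections,
                                     branch_set))
        for bid, (a, b) in layout.branch_segments.items():
            ax.plot([a[0], b[0]], [a[1], b[1]], color="black", lw=2,
                    zorder=1)
        cc = layout.cell_coords
        if cc.size:
            if color_by == "gene":
                sc = ax.scatter(cc[:, 0], cc[:, 1], c=gvals, s=8,
                                cmap="viridis", vmin=float(np.min(gvals)),
                                vmax=expression_cap(gvals), zorder=2)
                fig.colorbar(sc, ax=ax, label=gene)
            elif labels is not None:
                colors = label_colors or auto_label_colors(list(labels))
                ax.scatter(cc[:, 0], cc[:, 1],
                           c=[colors[l] for l in labels], s=8, zorder=2)
            else:
                ax.scatter(cc[:, 0], cc[:, 1], c="gray", s=8, zorder=2)
    elif view == "stream":
        if geometry is None:
            raise ValueError("stream view needs a StreamGeometry")
        if color_by == "gene":
            cap = None
            cell_branch = np.array([p.branch_id for p in projections])
            win_means = {}
            for bid, grid in geometry.grids.items():
                on_b = cell_branch == bid
                means = np.zeros(grid.size)
                halfw = geometry.window / 2
                for k, x in enumerate(grid):
                    sel = on_b & (np.asarray(pt) >= x - halfw) \
                        & (np.asarray(pt) <= x + halfw)
                    means[k] = gvals[sel].mean() if sel.any() else 0.0
                win_means[bid] = means
            cap = expression_cap(np.concatenate(list(win_means.values())))
            cmap = plt.get_cmap("viridis")
            for (bid, lab), poly in geometry.polygons.items():
                grid = geometry.grids[bid]
                m = win_means[bid]
                if grid.size >= 4:
                    f = interp1d(grid, m, kind="cubic")
                    m = f(grid)
                npts = grid.size
                lower, upper = poly[:npts], poly[npts:][::-1]
                vmax = cap if cap > 0 else 1.0
                for k in range(npts - 1):
                    ax.fill(
                        [grid[k], grid[k + 1], grid[k + 1], grid[k]],
                        [lower[k, 1], lower[k + 1, 1],
                         upper[k + 1, 1], upper[k, 1]],
                        color=cmap(min(m[k] / vmax, 1.0)), lw=0)
        else:
            if labels is not None:
                colors = label_colors or auto_label_colors(list(labels))
            else:
                colors = {lab: "#808080" for lab in geometry.labels}
            for (bid, lab), poly in geometry.polygons.items():
                ax.fill(poly[:, 0], poly[:, 1],
                        color=colors.get(lab, "#808080"), lw=0,
                        label=lab)
    else:
        raise ValueError(f"unknown view {view!r}")
    ax.set_xlabel("pseudotime" if view != "flat" else "")
    ax.set_yticks([])
    return _save(fig, path)
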