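"""Render the three tree views: flat tree, subway map, and stream plot.

Writes flat.png, subway.png, stream.png and stream_gene.png into the
current directory.
"""

import elastree as et
from elastree.stream_viz import render, smooth_and_assemble, \
    window_densities

matrix, truth = et.y_tree_fixture(seed=42)
res = et.run_pipeline(matrix, config=et.RunConfig(random_seed=42))

render("flat", "flat.png", tree=res.tree, branch_set=res.branch_set,
       projections=res.projections, labels=matrix.cell_labels,
       label_colors=matrix.label_colors)
print("flat.png: branches as straight length-preserving segments, cells "
      "beside their branch at their true orthogonal distance")

render("subway", "subway.png", tree=res.tree, branch_set=res.branch_set,
       projections=res.projections, root_state=res.root_state,
       labels=matrix.cell_labels, label_colors=matrix.label_colors)
print("subway.png: x is pseudotime from the root, branches in BFS lanes")

raw = window_densities(res.branch_set, res.projections, res.pseudotime,
                       labels=matrix.cell_labels,
                       root_state=res.root_state)
geom = smooth_and_assemble(raw)
render("stream", "stream.png", geometry=geom, labels=matrix.cell_labels,
       label_colors=matrix.label_colors)
print("stream.png: ribbon width = label-stratified cell density along "
      "pseudotime")

gene = truth.diverging_markers[0][0]
render("stream", "stream_gene.png", geometry=geom,
       projections=res.projections, pt=res.pseudotime,
       color_by="gene", gene=gene, expr=matrix.values,
       gene_names=matrix.feature_names)
print(f"stream_gene.png: ribbon colored by {gene} expression "
      "(colormap capped at the 90th percentile)")
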