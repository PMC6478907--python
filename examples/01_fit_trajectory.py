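"""Fit a principal tree to tree-structured single-cell expression data.

Generates the two-bifurcation benchmark (750 cells, 200 genes, three
time-point labels), runs the full default pipeline, and reports the
recovered topology and pseudotime accuracy against the known truth.
"""

from scipy.stats import spearmanr

import elastree as et

matrix, truth = et.tri_timepoint_fixture(seed=42)
print(f"input: {matrix.n_features} genes x {matrix.n_cells} cells, "
      f"labels {sorted(set(matrix.cell_labels))}")

result = et.run_pipeline(matrix, config=et.RunConfig(random_seed=42))

deg = result.tree.degrees()
print(f"fitted tree: {result.tree.n_nodes} nodes, "
      f"{(deg >= 3).sum()} branching nodes "
      f"(the benchmark has 2 bifurcations)")
print(f"branches: {sorted(result.branch_set.branches)}")
print(f"root state: {result.root_state} "
      "(leaf most enriched for the earliest label, T1)")

rho = spearmanr(truth.cell_pseudotime, result.pseudotime).statistic
print(f"Spearman rho, true vs inferred pseudotime: {rho:.3f}")
print("rho near 1 means the geodesic ordering along the fitted tree "
      "recovers the true developmental ordering.")
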