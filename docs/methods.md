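# Methods

This note records the models, numerical choices and open design
decisions behind `elastree`, in the order the pipeline runs them.

## Preprocessing and feature selection

Raw count matrices are library-size normalized so every cell's total
equals the **median library size** (the target is configurable), then
transformed with log2(x+1); the +1 pseudocount maps zeros to zero.
Variable genes are those whose standard deviation exceeds a local
regression fit of sd on mean across genes. Two deviations from common
practice are deliberate:

* the fit uses statsmodels' lowess, which is **locally linear
  (degree 1)**, fraction 0.3 — no degree-2 LOESS implementation is
  available in the dependency set;
* robustness iterations are disabled (`it=0`): when most genes sit
  exactly on the trend the median absolute residual collapses to zero
  and the robust weights degenerate, making the fit interpolate the
  very outliers the procedure is meant to find.

The selection cutoff — residual above the 95th percentile of all
residuals, floored at a numerical-noise threshold of `1e-8·max(sd)` —
is a package choice; no numeric cutoff is standard for "significantly
above the curve". For signed matrices (accessibility z-scores) where
the mean–sd relation is meaningless, `select_top_pcs` standardizes
features and takes leading principal components, optionally dropping
PC1 (which in accessibility data tends to track depth/technical noise).

## Embedding

`fit_mlle` wraps scikit-learn's modified locally linear embedding with
a neighborhood of 10% of the cells (at least d+1) and d=3 by default —
three components capture the main structure of typical datasets while
remaining directly visualizable. The per-dimension sign is fixed by
forcing the largest-magnitude coordinate positive, so repeated runs are
bit-identical. The sum-to-one constrained least-squares weight solve
(the single-vector reconstruction underlying LLE) is implemented
in-package because the out-of-sample mapping consumes it; the local
Gram matrix gets a ridge `ε = 1e-3·trace/k` when its condition number
exceeds 1e12, and an exact duplicate of the query (zero Gram diagonal)
short-circuits to indicator weights, which reproduce the duplicate's
embedding exactly.

## Seeding

Cells are summarized by affinity-propagation exemplars (damping 0.75,
scikit-learn's median-similarity preference); non-convergence falls
back to seeded k-means with k = round(√n). The exemplar count is capped
at 50 — the grammar search is O(|V|) candidates per growth step, and a
seed larger than the node budget defeats growth. A Euclidean minimum
spanning tree over the exemplars (Kruskal with lexicographic
tie-breaks, implemented in-package for determinism) is the seed
topology. For high-dimensional embeddings, a tree fitted on the top L
components is lifted: first L coordinates copied, the rest set to the
mean of each node's assigned cells (k=5 nearest cells for empty
nodes), edges preserved.

## Elastic principal tree

The energy has three terms: trimmed mean squared distance of cells to
their nearest node (points beyond the trimming radius R₀ contribute
R₀²; the default R₀=∞ reduces this to plain MSD), an edge term with
per-edge weight λ + α(max(2, deg(u), deg(v)) − 2), and μ times the
squared deviation of each star center from its neighbors' mean.
Defaults: λ=0.02, μ=0.1, α=0.02. α multiplies the squared edge length
exactly as the weight formula above states; larger α suppresses
branching, and α=1 effectively freezes the branch count of the seed.

With the partition fixed the energy is quadratic in node coordinates;
the exact minimizer solves one |V|×|V| linear system per embedding
dimension (ridge 1e-9 if near-singular). Alternating partition and
solve decreases the energy monotonically — asserted over random
instances in the tests. Growth applies two grammar moves at every
site — attach a node to a node (placed at the mean of the node's
assigned cells, or extrapolated when empty) and bisect an edge — gives
each candidate 10 splitting iterations, accepts the minimum-energy
candidate (earliest site wins ties), and fully converges only the
winner. The node budget defaults to min(30, n_cells/10); node counts
are not standardized anywhere, and this scales the resolution of the
tree with dataset size while bounding the search.

## Refinement

Applied in the order prune → shift → finetune → extend; pruning first
avoids spending effort on branches that will be discarded.

* **Prune** iterates until stable, removing leaf branches with fewer
  than 5 assigned cells or arc length below 5% of total tree length
  (an absolute override exists). Degree-2 pass-through nodes created
  by a removal are retained.
* **Shift** moves each branching node to the argmax, over cells within
  a radius (default: mean edge length), of a Gaussian kernel density
  with bandwidth radius/2 evaluated at cell positions only — a
  discrete mode search that avoids continuous optimization.
* **Finetune** bisects the edges around each branching node
  (2 extra nodes per branching node by default) and re-optimizes only
  that star. The optimized star is accepted only if the mean
  orthogonal cell-to-tree distance does not increase; otherwise the
  plain midpoint insertion is kept. Without this guard the elastic
  penalties can smooth away the local detail the extra nodes exist to
  capture.
* **Extend** appends a node beyond each leaf along the leaf's outward
  direction, at the 95th percentile of its cells' projections past the
  leaf, so terminal cells stop piling onto one node with identical
  pseudotime.

## Branches, pseudotime, layouts

States (nodes of degree ≠ 2) are named S0, S1, … in node-id order —
deterministic naming replaces any arbitrary starting choice so runs
are comparable. Branches are maximal degree-2 paths between states.
Cells project to the nearest point of any edge segment (ties to the
lexicographically first branch id); pseudotime is the geodesic
distance from the root to the projection point. The default root is
the terminal state of the leaf branch most enriched for the earliest
label (labels ordered by sorted name), else the longest-path leaf.

The flat-tree layout places states by stress majorization on the tree's
geodesic distances (weights 1/d², adjacent pairs up-weighted 10×) from
a seeded random start; drawn branch lengths track embedding branch
lengths to within a few percent, which is the property the view
promises. Cells sit at their arc-length offset, displaced laterally by
their true orthogonal distance on a seeded random side. The subway
layout uses pseudotime as x and stacks children in BFS lanes.

## Stream plots

Per branch and label, cell counts in sliding windows (window = 10% of
the longest root-to-leaf path, stride = half a window), normalized by
the longest-path length. Windows overhanging a branch's start count
parent-branch cells split across siblings **proportionally to each
child's occupancy of its first window** (equal split if empty) — the
paper-level description says only that the window spans parent and
children; proportional splitting is the choice that conserves counts.
Symmetrically, a parent's end windows count all children's cells in
full. Width curves are linearly interpolated to a uniform grid,
smoothed with a Savitzky–Golay filter (window 11, order 3, shrunk to
the nearest valid odd size on short branches), clipped at zero and
stacked into per-label polygons; lanes are packed greedily with a gap
of 20% of the tallest ribbon. Gene-colored views cap the colormap at
the 90th percentile of the plotted values, so single outliers cannot
flatten the scale.

## Markers

All detectors min–max scale expression to [0,1] over exactly the cells
entering the test, making decisions invariant to affine rescaling.
Fold changes use log2((m₁+ε)/(m₂+ε)) with ε=0.01 on the scaled scale to
tolerate zero means.

* **Diverging**: per branch pair sharing a state, an |log2 FC| > 0.25
  gate then a Mann–Whitney U standardized to Z with the tie-corrected
  σ_U = √(nᵢnⱼ/12 · ((n+1) − Σ(t³−t)/(n(n−1)))); |z| ≥ 2 detects. With
  fewer than 20 cells in either branch the rank test is underpowered
  and the fold-change gate alone decides.
* **Transition**: per branch, FC gate between the first 20% and last
  80% of cells by pseudotime (absolute FC — both activation and
  repression are biologically meaningful), then |Spearman ρ| ≥ 0.4
  over the branch's cells.
* **Leaf**: per gene, Z-scores of per-leaf-branch means (population
  sd); the max-|z| leaf is a candidate if |z| > 1.5, confirmed by
  Kruskal–Wallis p < 0.01 and all candidate-vs-other Conover pairwise
  p < 0.01 (in-package Conover–Iman: rank sums from the pooled KW
  ranking, tie-corrected variance, two-sided t p-values). **Structural
  limit**: with exactly 3 leaf branches the maximum attainable |z| is
  √2 ≈ 1.414 < 1.5, so no gene can be a leaf gene on a simple Y-shaped
  tree regardless of effect size; at least 4 leaves are needed for the
  default gate. With 2 leaves the detector falls back to the pairwise
  diverging test.

No multiple-testing correction is applied by default — detection uses
fixed statistic thresholds; a Benjamini–Hochberg option exists on the
statistics the detectors report.

## Mapping

New cells measured with the same features and normalization are placed
by locally linear reconstruction: K nearest reference cells (K
defaults to the reference's neighborhood size), radius r = the largest
of those K distances, neighbor set J = all reference cells within r,
the single-vector sum-to-one weight solve over J, and the embedding
coordinate Σⱼ wⱼ·vⱼ. The single-vector solve (not the multi-vector
embedding set) is used because one weight per neighbor is consumed;
weights sum to one by construction, so no re-normalization question
arises when |J| > K. Cells whose nearest reference distance exceeds 3×
the reference's 99th-percentile nearest-neighbor distance are flagged
out-of-reference — mapping cannot invent fates absent from the
reference. The reference embedding and tree are never modified.

## Accessibility track

Peaks are scored for presence of each canonical k-mer (k=7; a k-mer
and its reverse complement collapse to the lexicographically smaller,
N-containing windows skipped). Per k-mer and cell, the raw deviation is
(observed − expected)/expected with expected = cell total × the global
fraction of reads in the k-mer's peaks. Each k-mer's deviation is
standardized against 50 background peak sets, sampled peak-for-peak
from the same (mean accessibility, GC content) decile bin —a
simplified, documented stand-in for bias-corrected background
matching; it preserves the property that matters here (background sets
share the accessibility and GC profile of the foreground). Zero-read
cells are dropped with a warning. The z-score matrix is standardized
per k-mer and reduced by PCA with PC1 excluded (technical noise)
before entering the standard pipeline.

## Synthetic data

`make_tree_data` states a world: cells uniformly positioned along a
known branch topology; every gene's mean drifts linearly along each
branch, continuous at junctions; i.i.d. Gaussian noise (sd 0.3) on
top, generated directly on the post-normalization log scale. Structure
genes carry random drift slopes (sd 1.0 — about a 2-fold change per
branch, ordinary for developmental programs); planted diverging /
transition / leaf markers use a slope producing a 2.0 log2-unit change
(a 4-fold effect, typical of the marker genes that define hematopoietic
branch decisions) on their designated branch only; 30% of genes are
flat nulls for false-positive accounting. The tri-timepoint benchmark
is 5 branches (two nested bifurcations), 150 cells/branch, 200 genes,
labels T1/T2/T3 by branch generation. Randomness uses the counter-based
Philox generator, so fixtures regenerate bit-identically across
platforms.

What the generator does **not** emulate: dropout/UMI count noise,
batch effects, doublets, or library-size variation (expression is
generated post-normalization). A green test on these fixtures
establishes that the algorithms recover structure they are designed
for at realistic signal-to-noise; it does not establish robustness to
the technical artifacts of real experiments.

The toy accessibility fixture inserts one 7-mer into 20% of random
50-bp peaks and multiplies the Poisson rate of those peaks by 2 in half
the cells.

## Known limitations

* Tree topologies only — no cycles or disconnected forests.
* The grammar search is greedy per node count; it can in principle
  lock into a suboptimal topology that refinement cannot fully undo.
* Leaf-gene detection is structurally blind on trees with 3 leaf
  branches (see above).
* The flat-tree layout optimizes a stress objective; exact branch
  lengths are guaranteed only within a few percent, not to machine
  precision.
* Background matching in the accessibility track bins on observed GC
  and mean accessibility; it does not model Tn5 insertion bias.
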