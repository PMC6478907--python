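"""Deterministic projection of new cells onto a frozen reference tree.

New cells measured with the same features, normalization and protocol as
the reference are placed into the reference embedding by locally linear
reconstruction: find the K nearest reference cells in feature space, take
the largest of those distances as a radius r, gather every reference cell
within r, solve the sum-to-one constrained least squares for weights over
that neighborhood, and set the new embedding coordinate to the weighted
sum of the neighbors' embedding vectors. The reference embedding and tree
are never modified, so reference pseudotime keeps its meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .mlle import Embedding, solve_weights
from .tree_coords import (BranchSet, extract_branches, project_cells,
                          pseudotime)

__all__ = ["MappedCells", "map_cells"]


@dataclass
class MappedCells:
    coords: np.ndarray                  # new cells x d in reference embedding
    radius: np.ndarray                  # per-cell neighborhood radius
    neighbor_sets: list[np.ndarray]     # reference ids within radius
    weights: list[np.ndarray]           # sum-to-one weights per cell
    branch_ids: list[str]
    positions: np.ndarray               # arc-length offset on branch
    dists: np.ndarray                   # orthogonal distance to branch
    pseudotime: np.ndarray | None
    out_of_reference: np.ndarray        # bool flag per cell

    def branch_proportions(self) -> dict[str, float]:
        ids, counts = np.unique(self.branch_ids, return_counts=True)
        total = counts.sum()
        return {str(b): float(c) / total for b, c in zip(ids, counts)}


def map_cells(new_X: np.ndarray, ref: Embedding, tree,
              K: int | None = None, root_state: str | None = None,
              branch_set: BranchSet | None = None,
              random_seed: int = 0) -> MappedCells:
    """Map new cells into a reference embedding and onto its tree.

    ``K`` defaults to the neighborhood size used to build the reference.
    Cells whose nearest-neighbor distance exceeds 3x the reference's
    99th-percentile neighbor distance are flagged out-of-reference: their
    placement is still reported but may not be meaningful if they follow
    fates absent from the reference.
    """
    new_X = np.asarray(new_X, float)
    Y = ref.source_coords
    if new_X.ndim != 2 or new_X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"new cells have {new_X.shape[1] if new_X.ndim == 2 else '?'} "
            f"features but the reference was built on {Y.shape[1]}"
        )
    if K is None:
        K = ref.n_neighbors
    if K > Y.shape[0]:
        raise ValueError(f"K={K} exceeds reference size {Y.shape[0]}")

    D = cdist(new_X, Y)
    order = np.argsort(D, axis=1, kind="stable")

    # reference scale for the out-of-reference flag
    ref_nn = np.sort(cdist(Y, Y), axis=1)[:, 1]
    oor_limit = 3.0 * np.percentile(ref_nn, 99)

    n = new_X.shape[0]
    coords = np.zeros((n, ref.d))
    radius = np.zeros(n)
    nbr_sets: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    oor = np.zeros(n, dtype=bool)
    for i in range(n):
        knn = order[i, :K]
        r = D[i, knn].max()
        radius[i] = r
        J = np.flatnonzero(D[i] <= r)
        if J.size < 2:
            J = order[i, :2]
        G = _local_gram_query(new_X[i], Y, J)
        w = solve_weights(G)
        coords[i] = w @ ref.coords[J]
        nbr_sets.append(J)
        weights.append(w)
        oor[i] = D[i, knn[0]] > oor_limit

    if branch_set is None:
        branch_set = extract_branches(tree)
    projections = project_cells(tree, coords, branch_set,
                                random_seed=random_seed)
    pt = None
    if root_state is not None:
        pt = pseudotime(tree, projections, root_state, branch_set)
    return MappedCells(
        coords=coords, radius=radius, neighbor_sets=nbr_sets,
        weights=weights,
        branch_ids=[p.branch_id for p in projections],
        positions=np.array([p.position for p in projections]),
        dists=np.array([p.dist for p in projections]),
        pseudotime=pt, out_of_reference=oor,
    )


def _local_gram_query(query: np.ndarray, Y: np.ndarray,
                      neighbor_ids: np.ndarray) -> np.ndarray:
    diffs = Y[neighbor_ids] - query[None, :]
    return diffs @ diffs.T
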