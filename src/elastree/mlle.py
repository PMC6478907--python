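"""Modified Locally Linear Embedding (MLLE) and local reconstruction weights.

Each cell is reconstructed from its k nearest neighbors with sum-to-one
weight vectors; the embedding minimizes the reconstruction cost of those
weights in the low-dimensional space subject to an orthonormality
constraint. MLLE stabilizes standard LLE by using multiple linearly
independent weight vectors per neighborhood instead of a single one.

The embedding fit delegates to scikit-learn's implementation of the
algorithm; the single-vector constrained least-squares weight solve is
implemented here because it is reused verbatim by the out-of-sample
mapping procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import LocallyLinearEmbedding
from sklearn.neighbors import NearestNeighbors

__all__ = ["WeightSet", "Embedding", "solve_weights",
           "reconstruction_weights", "fit_mlle", "embedding_cost"]

#: Gram-matrix condition number beyond which ridge regularization kicks in
_COND_LIMIT = 1e12


@dataclass
class WeightSet:
    """Reconstruction weights of one query point from its neighbors."""

    neighbor_ids: np.ndarray          # (k,)
    optimal: np.ndarray               # (k,) the single constrained-LS vector
    vectors: np.ndarray               # (s, k) linearly independent vectors

    def __post_init__(self) -> None:
        assert abs(self.optimal.sum() - 1.0) < 1e-8
        assert self.vectors.shape[0] <= self.neighbor_ids.size


@dataclass
class Embedding:
    """Low-dimensional coordinates plus the machinery for out-of-sample mapping."""

    coords: np.ndarray                # cells x d
    source_coords: np.ndarray         # cells x features (the fitting space)
    n_neighbors: int
    neighbor_index: np.ndarray        # cells x k neighbor ids (self excluded)
    d: int

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _local_gram(X: np.ndarray, query: np.ndarray,
                neighbor_ids: np.ndarray) -> np.ndarray:
    diffs = X[neighbor_ids] - query[None, :]
    return diffs @ diffs.T


def solve_weights(G: np.ndarray) -> np.ndarray:
    """Solve the sum-to-one constrained least squares on a local Gram matrix.

    Minimizing ``||x - sum_j w_j x_j||`` subject to ``sum_j w_j = 1`` reduces
    to solving ``G w = 1`` and rescaling. A ridge ``eps*I`` with
    ``eps = 1e-3 * trace(G)/k`` is added when G is numerically singular.
    """
    k = G.shape[0]
    # exact duplicates of the query: zero diagonal entries admit a
    # zero-error reconstruction, so weight them directly
    diag = np.diag(G)
    exact = diag <= 1e-15 * max(np.trace(G), 1e-300)
    if exact.any():
        w = np.zeros(k)
        w[exact] = 1.0 / exact.sum()
        return w
    Greg = G
    cond = np.linalg.cond(G) if np.any(G) else np.inf
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        eps = 1e-3 * (np.trace(G) / k if np.trace(G) > 0 else 1.0)
        Greg = G + eps * np.eye(k)
        warnings.warn("singular local Gram matrix; ridge-regularized solve")
    w = np.linalg.solve(Greg, np.ones(k))
    return w / w.sum()


def reconstruction_weights(X: np.ndarray, query_index: int,
                           neighbor_ids) -> WeightSet:
    """Optimal single weight vector plus the multi-vector MLLE set.

    The additional vectors come from the bottom eigenvectors of the local
    Gram matrix (the near-null directions of the neighborhood difference
    matrix), recentred so every vector sums to one.
    """
    neighbor_ids = np.asarray(neighbor_ids, dtype=int)
    k = neighbor_ids.size
    if k < 2:
        raise ValueError("need at least 2 neighbors")
    if query_index in neighbor_ids:
        raise ValueError("neighbors must be distinct from the query point")
    G = _local_gram(X, X[query_index], neighbor_ids)
    w_opt = solve_weights(G)

    d_intrinsic = min(X.shape[1], k - 1)
    s = max(1, k - d_intrinsic)
    evals, evecs = np.linalg.eigh(G)
    vectors = [w_opt]
    for l in range(min(s - 1, k - 1)):
        u = evecs[:, l]
        u = u - u.mean()           # zero-sum perturbation keeps sum(w) = 1
        if np.linalg.norm(u) > 1e-12:
            vectors.append(w_opt + u)
    return WeightSet(neighbor_ids=neighbor_ids, optimal=w_opt,
                     vectors=np.array(vectors))


def fit_mlle(X: np.ndarray, d: int = 3,
             neighbor_fraction: float = 0.10) -> Embedding:
    """Embed cells x features data into d dimensions with MLLE.

    The neighborhood size is ``round(neighbor_fraction * n_cells)``
    (default 10% of cells) and must be at least d+1. The solution is
    deterministic up to global sign; the sign of each embedding column is
    fixed so the first cell's coordinate is non-negative.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= d + 1:
        raise ValueError(f"need more than {d + 1} cells for a {d}-D embedding")
    k = int(round(neighbor_fraction * n))
    if k < d + 1:
        raise ValueError(
            f"neighborhood of {k} cells is below d+1={d + 1}; increase "
            "neighbor_fraction"
        )
    k = min(k, n - 1)
    lle = LocallyLinearEmbedding(
        n_neighbors=k, n_components=d, method="modified",
        eigen_solver="dense", random_state=0,
    )
    T = lle.fit_transform(X)
    # stabilize global sign per dimension
    for j in range(d):
        anchor = T[:, j][np.argmax(np.abs(T[:, j]))]
        if anchor < 0:
            T[:, j] = -T[:, j]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    return Embedding(coords=T, source_coords=X, n_neighbors=k,
                     neighbor_index=idx, d=d)


def embedding_cost(X: np.ndarray, T: np.ndarray, n_neighbors: int) -> float:
    """Single-vector LLE embedding cost of coordinates T for data X.

    Serves as an independent oracle: the fitted embedding should score no
    worse than random orthonormal coordinate systems under this cost.
    """
    X = np.asarray(X, float)
    T = np.asarray(T, float)
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    cost = 0.0
    for i in range(n):
        w = solve_weights(_local_gram(X, X[i], idx[i]))
        cost += float(np.sum((T[i] - w @ T[idx[i]]) ** 2))
    return cost
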