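"""Branch marker detection: diverging, transition, and leaf features.

All detectors operate on a fitted (or ground-truth) branch annotation:
which branch each cell sits on, its pseudotime, and which branches share a
state. Expression is min-max scaled to [0, 1] over exactly the cells
involved in each test, which makes every decision invariant to affine
rescaling of the raw values.

* Diverging features differ between a pair of branches meeting at a
  state: a log2 fold-change gate on the scaled means followed by a
  tie-corrected Mann-Whitney U test standardized to a Z-score (branches
  with fewer than 20 cells fall back to the fold-change gate alone).
* Transition features vary along a single branch: a fold-change gate
  between the first 20% and last 80% of cells by pseudotime, then Spearman
  correlation of expression with pseudotime.
* Leaf features are specific to one terminal branch: Z-score of the
  candidate leaf's mean across leaf means, a Kruskal-Wallis test across
  leaves, and pairwise Conover post-hoc tests of the candidate against
  every other leaf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BranchAnnotation", "DivergingResult", "TransitionResult", "LeafResult",
    "mannwhitney_z", "detect_diverging", "detect_transition", "detect_leaf",
    "conover_pairwise",
]

#: pseudocount on the [0,1] scale for fold changes with zero means
_EPS = 0.01
#: branches smaller than this fall back to the fold-change-only rule
_SMALL_SAMPLE = 20


@dataclass
class BranchAnnotation:
    """Cell-to-branch assignment plus the tree relations detectors need."""

    branch_ids: list[str]
    cell_branch: np.ndarray            # str per cell
    cell_pseudotime: np.ndarray
    branch_states: dict[str, tuple[str, str]]   # branch -> endpoint states
    leaf_branch_ids: list[str]

    @classmethod
    def from_tree(cls, branch_set, projections, pt) -> "BranchAnnotation":
        deg = branch_set.state_degrees()
        return cls(
            branch_ids=sorted(branch_set.branches),
            cell_branch=np.array([p.branch_id for p in projections]),
            cell_pseudotime=np.asarray(pt, float),
            branch_states={bid: b.states
                           for bid, b in branch_set.branches.items()},
            leaf_branch_ids=sorted(branch_set.leaf_branches(deg)),
        )

    def branch_pairs(self) -> list[tuple[str, str]]:
        """Branch pairs sharing an endpoint state, lexicographic order."""
        pairs = []
        bids = self.branch_ids
        for i in range(len(bids)):
            for j in range(i + 1, len(bids)):
                if set(self.branch_states[bids[i]]) & set(
                        self.branch_states[bids[j]]):
                    pairs.append((bids[i], bids[j]))
        return pairs

    def cells_on(self, bid: str) -> np.ndarray:
        return np.flatnonzero(self.cell_branch == bid)


@dataclass
class DivergingResult:
    gene: str
    branch_pair: tuple[str, str]
    mean_i: float
    mean_j: float
    log2_fc: float
    U: float
    z: float
    small_sample: bool
    detected: bool


@dataclass
class TransitionResult:
    gene: str
    branch: str
    early_mean: float
    late_mean: float
    log2_fc: float
    rho: float
    detected: bool


@dataclass
class LeafResult:
    gene: str
    leaf_means: dict[str, float]
    leaf_zscores: dict[str, float]
    candidate: str | None
    kw_pvalue: float
    conover_pvalues: dict[str, float]
    detected: bool


def mannwhitney_z(x, y) -> tuple[float, float]:
    """Mann-Whitney U of x vs y and its tie-corrected Z-score.

    U is the rank-sum statistic of x in the pooled ranking; the Z-score is
    (U - m_U)/sigma_U with m_U = n_i n_j / 2 and the tie-corrected

        sigma_U = sqrt( n_i n_j / 12 * ((n+1) - sum_l (t_l^3 - t_l)/(n(n-1))) )

    where t_l counts the values sharing tied rank l. When every value is
    tied sigma_U is 0 and z is defined as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ni, nj = x.size, y.size
    n = ni + nj
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    U = float(ranks[:ni].sum() - ni * (ni + 1) / 2)
    m_U = ni * nj / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_sum = float(((t ** 3 - t) / (n * (n - 1))).sum()) if n > 1 else 0.0
    var = ni * nj / 12.0 * ((n + 1) - tie_sum)
    if var <= 0:
        return U, 0.0
    return U, float((U - m_U) / np.sqrt(var))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _log2_fc(mean_i: float, mean_j: float) -> float:
    return float(np.log2((mean_i + _EPS) / (mean_j + _EPS)))


def detect_diverging(expr: np.ndarray, genes: list[str],
                     ann: BranchAnnotation, fc_threshold: float = 0.25,
                     z_threshold: float = 2.0) -> list[DivergingResult]:
    """Differential features between every pair of branches sharing a state.

    Per pair and gene: pool the two branches' cells, scale to [0, 1],
    require |log2 FC of means| > fc_threshold, then |z| >= z_threshold
    (fold-change gate alone when either branch has < 20 cells). Results
    sorted by |z| descending.
    """
    results: list[DivergingResult] = []
    for bi, bj in ann.branch_pairs():
        ci, cj = ann.cells_on(bi), ann.cells_on(bj)
        if ci.size == 0 or cj.size == 0:
            warnings.warn(f"branch pair ({bi}, {bj}) has an empty branch; "
                          "skipped")
            continue
        small = ci.size < _SMALL_SAMPLE or cj.size < _SMALL_SAMPLE
        for gi, gene in enumerate(genes):
            pooled = _minmax(np.concatenate([expr[gi, ci], expr[gi, cj]]))
            vi, vj = pooled[:ci.size], pooled[ci.size:]
            mi, mj = float(vi.mean()), float(vj.mean())
            fc = _log2_fc(mi, mj)
            if abs(fc) <= fc_threshold:
                U, z = np.nan, np.nan
                detected = False
            else:
                U, z = mannwhitney_z(vi, vj)
                detected = small or abs(z) >= z_threshold
            results.append(DivergingResult(
                gene=gene, branch_pair=(bi, bj), mean_i=mi, mean_j=mj,
                log2_fc=fc, U=U, z=z, small_sample=small,
                detected=bool(detected)))
    results.sort(key=lambda r: -(abs(r.z) if np.isfinite(r.z) else -np.inf))
    return results


def detect_transition(expr: np.ndarray, genes: list[str],
                      ann: BranchAnnotation, fc_threshold: float = 0.25,
                      rho_threshold: float = 0.4) -> list[TransitionResult]:
    """Features correlated with pseudotime along each branch.

    Per branch and gene: scale the branch's cells to [0, 1], gate on the
    |log2 FC| between the first 20% and the last 80% of cells by
    pseudotime, then require |Spearman rho| >= rho_threshold over all the
    branch's cells. Branches with fewer than 5 cells are skipped.
    """
    results: list[TransitionResult] = []
    for bid in ann.branch_ids:
        cells = ann.cells_on(bid)
        if cells.size < 5:
            continue
        order = cells[np.argsort(ann.cell_pseudotime[cells],
                                 kind="stable")]
        n_early = max(1, int(np.floor(0.2 * cells.size)))
        early, late = order[:n_early], order[n_early:]
        pt = ann.cell_pseudotime[cells]
        for gi, gene in enumerate(genes):
            scaled_all = _minmax(expr[gi, cells])
            lookup = dict(zip(cells.tolist(), scaled_all))
            e_mean = float(np.mean([lookup[c] for c in early]))
            l_mean = float(np.mean([lookup[c] for c in late]))
            fc = _log2_fc(l_mean, e_mean)
            if abs(fc) <= fc_threshold:
                results.append(TransitionResult(
                    gene=gene, branch=bid, early_mean=e_mean,
                    late_mean=l_mean, log2_fc=fc, rho=np.nan,
                    detected=False))
                continue
            if np.ptp(scaled_all) == 0 or np.ptp(pt) == 0:
                rho = 0.0
            else:
                rho = float(stats.spearmanr(pt, scaled_all).statistic)
            results.append(TransitionResult(
                gene=gene, branch=bid, early_mean=e_mean, late_mean=l_mean,
                log2_fc=fc, rho=rho,
                detected=bool(abs(rho) >= rho_threshold)))
    results.sort(key=lambda r: -(abs(r.rho) if np.isfinite(r.rho)
                                 else -np.inf))
    return results


def conover_pairwise(groups: list[np.ndarray]) -> np.ndarray:
    """Two-sided Conover-Iman post-hoc p-values from the pooled KW ranking.

    Uses rank sums from the Kruskal-Wallis ranking and t-distribution
    p-values with the tie-corrected pooled variance.
    """
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    rank_means = []
    start = 0
    for sz in sizes:
        rank_means.append(ranks[start:start + sz].mean())
        start += sz
    rank_means = np.array(rank_means)
    H = stats.kruskal(*groups).statistic if k > 1 else 0.0
    _, t = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - ((t ** 3 - t).sum() / (n ** 3 - n)) if n > 1 else 1.0
    s2 = (n * (n + 1) / 12.0) * tie_factor
    df = n - k
    pvals = np.ones((k, k))
    if df <= 0 or s2 <= 0:
        return pvals
    denom_scale = s2 * (n - 1 - H) / df
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(denom_scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                tstat = abs(rank_means[i] - rank_means[j]) / se
                p = 2 * stats.t.sf(tstat, df)
            pvals[i, j] = pvals[j, i] = p
    return pvals


def detect_leaf(expr: np.ndarray, genes: list[str], ann: BranchAnnotation,
                z_cut: float = 1.5, p_cut: float = 0.01) -> list[LeafResult]:
    """Features specific to one terminal (leaf) branch.

    Per gene: scale the leaf-branch cells to [0, 1]; Z-score the per-leaf
    means across leaves; the leaf of max |z| is the candidate if |z| >
    z_cut; Kruskal-Wallis across leaves must reject at p_cut, and every
    Conover comparison of the candidate against another leaf must too.
    Needs at least 3 leaf branches (with 2, use the diverging detector).
    """
    leaves = ann.leaf_branch_ids
    if len(leaves) < 3:
        warnings.warn("fewer than 3 leaf branches; falling back to the "
                      "pairwise diverging detector")
        res = detect_diverging(expr, genes, ann)
        return [LeafResult(gene=r.gene, leaf_means={}, leaf_zscores={},
                           candidate=r.branch_pair[0] if r.detected else None,
                           kw_pvalue=np.nan, conover_pvalues={},
                           detected=r.detected) for r in res]
    cell_sets = [ann.cells_on(b) for b in leaves]
    all_cells = np.concatenate(cell_sets)
    results: list[LeafResult] = []
    for gi, gene in enumerate(genes):
        scaled = _minmax(expr[gi, all_cells])
        groups = []
        start = 0
        for cs in cell_sets:
            groups.append(scaled[start:start + cs.size])
            start += cs.size
        means = np.array([g.mean() if g.size else np.nan for g in groups])
        sd = means.std(ddof=0)
        zs = np.zeros_like(means) if sd == 0 else (means - means.mean()) / sd
        order = int(np.argmax(np.abs(zs)))
        candidate = leaves[order] if abs(zs[order]) > z_cut else None
        kw_p = np.nan
        conover: dict[str, float] = {}
        detected = False
        if candidate is not None:
            try:
                kw_p = float(stats.kruskal(*groups).pvalue)
            except ValueError:      # all values identical
                kw_p = 1.0
            if kw_p < p_cut:
                P = conover_pairwise(groups)
                conover = {leaves[j]: float(P[order, j])
                           for j in range(len(leaves)) if j != order}
                detected = all(p < p_cut for p in conover.values())
        results.append(LeafResult(
            gene=gene,
            leaf_means={b: float(m) for b, m in zip(leaves, means)},
            leaf_zscores={b: float(z) for b, z in zip(leaves, zs)},
            candidate=candidate, kw_pvalue=kw_p,
            conover_pvalues=conover, detected=detected))
    return results
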