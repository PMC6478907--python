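"""Evaluation metrics: pseudotime correlations and branch precision/recall/F1.

Pseudotime quality against a known ordering is summarized by four
coefficients: Pearson r on the values, Pearson r of truth against the
ranks of the inferred pseudotime (useful when a method only reports
ranks), Spearman rho, and Kendall tau-a computed as the ordered-pair sign
sum normalized by n(n-1).

Branch quality on real data uses a pair of mutually exclusive marker
genes: the branch holding most cells expressing a gene is its branch;
recall, precision and F1 then quantify under-branching (merged branches:
recall stays 1, precision drops) versus over-branching (split branches:
precision stays 1, recall drops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationReport", "BranchF1Report",
           "pseudotime_correlations", "branch_f1"]


@dataclass
class CorrelationReport:
    r_pseudotime: float
    r_rank: float
    spearman_rho: float
    kendall_tau: float
    degenerate: bool      # constant input -> NaN coefficients, flagged


@dataclass
class GeneF1:
    gene: str
    branch: str | None
    tp: int
    fn: int
    fp: int
    recall: float
    precision: float
    f1: float
    no_expressing_cells: bool = False


@dataclass
class BranchF1Report:
    per_gene: dict[str, GeneF1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def pseudotime_correlations(truth, inferred) -> CorrelationReport:
    """Four agreement coefficients between true ordering and pseudotime."""
    x = np.asarray(truth, float)
    y = np.asarray(inferred, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 cells")
    degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
    if degenerate:
        warnings.warn("constant vector; correlation coefficients are NaN")
    r = _pearson(x, y)
    rg_y = stats.rankdata(y)
    r_rank = _pearson(x, rg_y)
    rho = (np.nan if degenerate
           else float(stats.spearmanr(x, y).statistic))
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    tau = float((sx * sy).sum() / (n * (n - 1)))
    if degenerate:
        tau = np.nan
    return CorrelationReport(r_pseudotime=r, r_rank=r_rank,
                             spearman_rho=rho, kendall_tau=tau,
                             degenerate=bool(degenerate))


def branch_f1(expr_gi, expr_gj, branch_assignment,
              gene_names=("Gi", "Gj"), expr_cutoff: float = 0.0
              ) -> BranchF1Report:
    """Precision/recall/F1 of a branching model for a marker-gene pair.

    A cell "expresses" a gene when its (scaled) value exceeds
    ``expr_cutoff``. For gene Gi: Bi is the branch with most
    Gi-expressing cells, TP the Gi-expressing cells on Bi, FN the
    Gi-expressing cells elsewhere, FP the Gj-expressing cells on Bi;
    symmetrically for Gj.
    """
    expr_gi = np.asarray(expr_gi, float)
    expr_gj = np.asarray(expr_gj, float)
    branches = np.asarray(branch_assignment)
    report: dict[str, GeneF1] = {}
    for name, own, other in ((gene_names[0], expr_gi, expr_gj),
                             (gene_names[1], expr_gj, expr_gi)):
        expressing = own > expr_cutoff
        if not expressing.any():
            warnings.warn(f"no cell expresses {name}; zero scores reported")
            report[name] = GeneF1(gene=name, branch=None, tp=0, fn=0, fp=0,
                                  recall=0.0, precision=0.0, f1=0.0,
                                  no_expressing_cells=True)
            continue
        ids, counts = np.unique(branches[expressing], return_counts=True)
        b = ids[np.argmax(counts)]
        on_b = branches == b
        tp = int((expressing & on_b).sum())
        fn = int((expressing & ~on_b).sum())
        fp = int(((other > expr_cutoff) & on_b).sum())
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if tp else 0.0)
        report[name] = GeneF1(gene=name, branch=str(b), tp=tp, fn=fn,
                              fp=fp, recall=recall, precision=precision,
                              f1=f1)
    return BranchF1Report(per_gene=report)
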