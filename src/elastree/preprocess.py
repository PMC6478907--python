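"""Normalization, log transform, and informative-feature selection.

Feature selection for expression data fits the mean/standard-deviation
relationship across genes with local regression and keeps genes whose
dispersion sits well above the fitted trend. For accessibility z-score
matrices (signed values), selection uses top principal components instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import AnnotatedMatrix

__all__ = [
    "normalize_and_log",
    "select_variable_genes",
    "select_top_pcs",
    "VariableGeneResult",
]


@dataclass
class VariableGeneResult:
    gene: str
    mean: float
    sd: float
    fitted_sd: float
    diverge_score: float  # sd - fitted_sd
    selected: bool


def normalize_and_log(m: AnnotatedMatrix, *, target_sum: float | None = None,
                      drop_empty_cells: bool = False) -> AnnotatedMatrix:
    """Library-size normalize each cell to the median library size, then log2(x+1).

    Each cell column is rescaled so its total equals the median
    pre-normalization library size (or ``target_sum``), after which
    log2(x + 1) is applied so zeros map to zero.
    """
    if m.normalized or m.log_transformed:
        raise ValueError("matrix already normalized/log-transformed")
    if np.any(m.values < 0):
        raise ValueError("normalize_and_log expects non-negative counts")
    totals = m.values.sum(axis=0)
    empty = np.flatnonzero(totals == 0)
    values = m.values
    cell_names = m.cell_names
    cell_labels = m.cell_labels
    if empty.size:
        if not drop_empty_cells:
            bad = [m.cell_names[i] for i in empty]
            raise ValueError(f"cells with zero total counts: {bad}")
        warnings.warn(f"dropping {empty.size} empty cells")
        keep = np.setdiff1d(np.arange(m.n_cells), empty)
        values = values[:, keep]
        cell_names = [m.cell_names[i] for i in keep]
        if cell_labels is not None:
            cell_labels = [cell_labels[i] for i in keep]
        totals = totals[keep]
    target = float(np.median(totals)) if target_sum is None else float(target_sum)
    scaled = values * (target / totals)[None, :]
    logged = np.log2(scaled + 1.0)
    return m.copy_with(values=logged, cell_names=cell_names,
                       cell_labels=cell_labels, normalized=True,
                       log_transformed=True)


def select_variable_genes(m: AnnotatedMatrix, loess_fraction: float = 0.3,
                          residual_cutoff_percentile: float = 95.0
                          ) -> list[VariableGeneResult]:
    """Select genes whose sd exceeds the local-regression fit of sd on mean.

    The sd-vs-mean trend is fitted by lowess across genes; genes whose
    residual (sd minus fitted sd) exceeds the given percentile of positive
    residuals are flagged. Results are sorted by residual, descending.
    Falls back to sd-rank selection when the trend fit is degenerate.
    """
    if not (m.normalized and m.log_transformed):
        raise ValueError("select_variable_genes expects a normalized, "
                         "log-transformed matrix")
    if m.n_features < 10:
        raise ValueError("need at least 10 genes")
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=0)

    if np.ptp(means) == 0:
        warnings.warn("degenerate mean distribution; falling back to "
                      "sd-rank selection")
        fitted = np.full_like(sds, float(np.median(sds)))
    else:
        # it=0: plain local regression; the robustness iterations degenerate
        # when most residuals are ~0 (median residual -> 0 collapses the
        # robust weights) and the fit then interpolates outliers
        fit = lowess(sds, means, frac=loess_fraction, it=0,
                     return_sorted=False)
        fitted = np.asarray(fit, dtype=float)
        if not np.all(np.isfinite(fitted)):
            warnings.warn("lowess fit failed; falling back to sd-rank "
                          "selection")
            fitted = np.full_like(sds, float(np.median(sds)))

    resid = sds - fitted
    # floor at numerical noise so an exact fit never yields "selected" genes
    tiny = 1e-8 * max(1.0, float(np.abs(sds).max()))
    cutoff = max(float(np.percentile(resid, residual_cutoff_percentile)),
                 tiny)
    results = [
        VariableGeneResult(gene=m.feature_names[i], mean=float(means[i]),
                           sd=float(sds[i]), fitted_sd=float(fitted[i]),
                           diverge_score=float(resid[i]),
                           selected=bool(resid[i] > cutoff))
        for i in range(m.n_features)
    ]
    results.sort(key=lambda r: -r.diverge_score)
    return results


def subset_features(m: AnnotatedMatrix,
                    results: list[VariableGeneResult]) -> AnnotatedMatrix:
    """Restrict a matrix to the selected genes of a variable-gene result."""
    keep = [r.gene for r in results if r.selected]
    idx = [m.feature_names.index(g) for g in keep]
    return m.copy_with(values=m.values[idx, :], feature_names=keep)


def select_top_pcs(m: AnnotatedMatrix, n_pcs: int,
                   exclude_first: bool = False) -> np.ndarray:
    """Cells x n_pcs principal-component scores of the standardized features.

    Features are standardized (zero mean, unit variance) before the
    decomposition. With ``exclude_first`` the returned scores are components
    2..n_pcs+1, dropping the leading component (commonly technical noise in
    accessibility data).
    """
    n_needed = n_pcs + (1 if exclude_first else 0)
    if n_needed >= min(m.n_features, m.n_cells):
        raise ValueError(
            f"requested {n_needed} components but matrix rank is at most "
            f"{min(m.n_features, m.n_cells)}"
        )
    X = m.values.T.astype(float)  # cells x features
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    pca = PCA(n_components=n_needed, svd_solver="full", random_state=0)
    scores = pca.fit_transform(Xs)
    return scores[:, 1:] if exclude_first else scores
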