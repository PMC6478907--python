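"""Core containers and readers/writers for expression matrices and labels.

The central container is :class:`AnnotatedMatrix`, a features x cells matrix
(genes x cells for RNA, peaks or k-mers x cells for chromatin accessibility)
carrying row/column names, optional per-cell labels with colors, and
processing provenance flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "AnnotatedMatrix",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "attach_labels",
    "auto_label_colors",
]

#: deterministic fallback palette for labels without a user-supplied color
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


class MatrixFormatError(ValueError):
    """Malformed input file (bad header, shape mismatch, missing sidecar)."""


class MatrixValidationError(ValueError):
    """Contract violation in matrix content (duplicate names, NaN, ...)."""


@dataclass
class AnnotatedMatrix:
    """Features x cells real matrix with names, labels and provenance flags."""

    values: np.ndarray
    feature_names: list[str]
    cell_names: list[str]
    cell_labels: Optional[list[str]] = None
    label_colors: Optional[dict[str, str]] = None
    log_transformed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be 2-dimensional")
        n_feat, n_cell = self.values.shape
        if n_feat != len(self.feature_names):
            raise MatrixValidationError(
                f"{n_feat} rows but {len(self.feature_names)} feature names"
            )
        if n_cell != len(self.cell_names):
            raise MatrixValidationError(
                f"{n_cell} columns but {len(self.cell_names)} cell names"
            )
        for kind, names in (("feature", self.feature_names),
                            ("cell", self.cell_names)):
            dupes = _duplicates(names)
            if dupes:
                raise MatrixValidationError(
                    f"duplicate {kind} names: {sorted(dupes)}"
                )
        if self.cell_labels is not None and len(self.cell_labels) != n_cell:
            raise MatrixValidationError(
                f"{n_cell} cells but {len(self.cell_labels)} labels"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **changes) -> "AnnotatedMatrix":
        return replace(self, **changes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names,
                            columns=self.cell_names)


def _duplicates(names: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        (dupes if n in seen else seen).add(n)
    return dupes


@dataclass
class RunConfig:
    """All pipeline parameters with validated defaults.

    Defaults follow the elastic-principal-graph convention: trimming radius
    infinite, edge-stretching modulus ``epg_lambda`` 0.02, star-bending
    modulus ``epg_mu`` 0.1, branching-control coefficient ``epg_alpha``
    0.02, affinity-propagation damping 0.75, MLLE neighborhood 10% of cells.
    """

    loess_fraction: float = 0.3
    residual_cutoff_percentile: float = 95.0
    mlle_components: int = 3
    mlle_neighbor_fraction: float = 0.10
    ap_damping: float = 0.75
    epg_alpha: float = 0.02
    epg_mu: float = 0.1
    epg_lambda: float = 0.02
    epg_trimming_radius: float = np.inf
    epg_n_nodes: Optional[int] = None  # None -> min(30, round(n_cells/10))
    min_branch_cells: int = 5
    min_branch_length_frac: float = 0.05
    finetune_n_nodes: int = 2
    extend_percentile: float = 95.0
    fc_threshold: float = 0.25
    z_threshold: float = 2.0
    rho_threshold: float = 0.4
    leaf_z_cut: float = 1.5
    leaf_p_cut: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.loess_fraction <= 1, "loess_fraction in (0, 1]"),
            (0 < self.residual_cutoff_percentile < 100,
             "residual_cutoff_percentile in (0, 100)"),
            (self.mlle_components >= 1, "mlle_components >= 1"),
            (0 < self.mlle_neighbor_fraction < 1,
             "mlle_neighbor_fraction in (0, 1)"),
            (0.5 <= self.ap_damping < 1, "ap_damping in [0.5, 1)"),
            (0 < self.epg_alpha <= 1, "epg_alpha in (0, 1]"),
            (self.epg_mu > 0, "epg_mu > 0"),
            (self.epg_lambda > 0, "epg_lambda > 0"),
            (self.epg_trimming_radius > 0, "epg_trimming_radius > 0"),
            (self.min_branch_cells > 0, "min_branch_cells > 0"),
            (self.min_branch_length_frac > 0, "min_branch_length_frac > 0"),
            (self.finetune_n_nodes >= 0, "finetune_n_nodes >= 0"),
            (0 < self.extend_percentile <= 100,
             "extend_percentile in (0, 100]"),
            (self.random_seed >= 0, "random_seed >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"RunConfig: expected {msg}")


def read_matrix(path, fmt: Optional[str] = None, *, transpose: bool = False,
                impute_zero: bool = False) -> AnnotatedMatrix:
    """Read a features x cells matrix from TSV/CSV (dense) or MTX (sparse).

    Dense files: first column feature names, first row cell names. Sparse
    MatrixMarket files expect ``features.tsv`` and ``cells.tsv`` sidecars in
    the same directory (a name per line; CellRanger-style extra columns are
    tolerated, the first is used).

    NaN entries are rejected unless ``impute_zero`` converts them to zero
    with a warning (silent NaN propagation corrupts the LOESS fit and the
    eigen-solvers downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        feature_names = [str(x) for x in df.index]
        cell_names = [str(x) for x in df.columns]
    elif fmt == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        values = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float)
        feature_names = _read_sidecar(path.parent / "features.tsv")
        cell_names = _read_sidecar(path.parent / "cells.tsv")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if transpose:
        values = values.T
        feature_names, cell_names = cell_names, feature_names

    n_nan = int(np.isnan(values).sum())
    if n_nan:
        if impute_zero:
            warnings.warn(f"imputed {n_nan} NaN entries to 0")
            values = np.nan_to_num(values, nan=0.0)
        else:
            raise MatrixValidationError(
                f"{n_nan} NaN entries in {path}; pass impute_zero=True to "
                "convert them to 0"
            )
    return AnnotatedMatrix(values=values, feature_names=feature_names,
                           cell_names=cell_names)


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise MatrixFormatError(f"missing sidecar name file {path}")
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                names.append(line.split("\t")[0])
    return names


def write_matrix(m: AnnotatedMatrix, path, fmt: Optional[str] = None) -> None:
    """Write a matrix as dense TSV/CSV or sparse MTX (+ name sidecars)."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv")
    if fmt in ("tsv", "csv"):
        m.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(m.values))
        for fname, names in (("features.tsv", m.feature_names),
                             ("cells.tsv", m.cell_names)):
            (path.parent / fname).write_text("\n".join(names) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def auto_label_colors(labels: list[str],
                      given: Optional[dict[str, str]] = None) -> dict[str, str]:
    """Deterministic label->hex map: user colors first, palette cycle after."""
    colors = dict(given or {})
    uniq = sorted(set(labels))
    i = 0
    for lab in uniq:
        if lab not in colors:
            colors[lab] = _PALETTE[i % len(_PALETTE)]
            i += 1
    return colors


def attach_labels(m: AnnotatedMatrix, labels_path,
                  colors_path=None) -> AnnotatedMatrix:
    """Attach one-per-line cell labels (in cell order) and optional colors.

    Colors file is a two-column TSV ``label<TAB>#rrggbb``; labels missing
    from it get deterministic auto-colors from a fixed palette.
    """
    labels = [ln.rstrip("\n") for ln in open(labels_path) if ln.strip()]
    if len(labels) != m.n_cells:
        raise MatrixValidationError(
            f"label file has {len(labels)} entries but matrix has "
            f"{m.n_cells} cells"
        )
    given = None
    if colors_path is not None:
        given = {}
        with open(colors_path) as fh:
            for line in fh:
                if line.strip():
                    lab, col = line.rstrip("\n").split("\t")[:2]
                    given[lab] = col
    return m.copy_with(cell_labels=labels,
                       label_colors=auto_label_colors(labels, given))
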