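"""Chromatin-accessibility features: k-mer matching and deviation z-scores.

Peaks are scored for the presence of every canonical k-mer (a k-mer and
its reverse complement are one feature; default k = 7). Per cell and
k-mer, a raw accessibility deviation compares the reads falling into
peaks containing the k-mer against the expectation under cell-uniform
accessibility; the deviation is standardized against background peak sets
matched on mean accessibility and GC content. The resulting cells x
k-mers z-score matrix is standardized and reduced by PCA (dropping the
first component, which tends to capture technical noise) before entering
the standard trajectory pipeline.

This is a simplified reimplementation of the deviation/z-score scheme
popularized for scATAC data: the background matching bins peaks on
(mean accessibility, GC) deciles rather than using a bias-corrected
nearest-neighbor sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import AnnotatedMatrix
from .preprocess import select_top_pcs

__all__ = ["PeakKmerMatrix", "DeviationMatrix", "canonical_kmer",
           "match_kmers", "kmer_deviations", "atac_feature_prep",
           "export_kmers_meme"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class PeakKmerMatrix:
    matrix: np.ndarray            # peaks x canonical k-mers, entries {0,1}
    peak_ids: list[str]
    kmers: list[str]              # canonical k-mer per column
    k: int
    gc_content: np.ndarray        # per-peak GC fraction

    def __post_init__(self) -> None:
        assert set(np.unique(self.matrix)) <= {0, 1}


@dataclass
class DeviationMatrix:
    zscores: np.ndarray           # cells x k-mers
    raw: np.ndarray               # cells x k-mers raw deviations
    kmers: list[str]
    cell_ids: list[str]
    n_background: int
    background_mean: np.ndarray   # cells x k-mers
    background_sd: np.ndarray


def match_kmers(peak_seqs: list[str], k: int = 7,
                peak_ids: list[str] | None = None) -> PeakKmerMatrix:
    """Presence/absence of every canonical k-mer in each peak sequence.

    A peak scores 1 for a k-mer if the k-mer or its reverse complement
    occurs in its sequence; windows containing N are ignored. Only k-mers
    observed in at least one peak become columns.
    """
    if not peak_seqs:
        raise ValueError("no peak sequences given")
    if peak_ids is None:
        peak_ids = [f"peak{i}" for i in range(len(peak_seqs))]
    presence: list[set[str]] = []
    gc = np.zeros(len(peak_seqs))
    for pi, seq in enumerate(peak_seqs):
        seq = seq.upper()
        acgt = [c for c in seq if c in "ACGT"]
        gc[pi] = (sum(c in "GC" for c in acgt) / len(acgt)) if acgt else 0.0
        found: set[str] = set()
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if any(c not in "ACGT" for c in window):
                continue
            found.add(canonical_kmer(window))
        presence.append(found)
    kmers = sorted(set().union(*presence))
    col = {km: j for j, km in enumerate(kmers)}
    M = np.zeros((len(peak_seqs), len(kmers)), dtype=np.int8)
    for pi, found in enumerate(presence):
        for km in found:
            M[pi, col[km]] = 1
    return PeakKmerMatrix(matrix=M, peak_ids=list(peak_ids), kmers=kmers,
                          k=k, gc_content=gc)


def _deviation(counts: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Raw deviations for one peak set across all cells.

    counts: peaks x cells; member: boolean peak mask. Expected reads for a
    cell are its total reads times the global fraction of reads falling in
    the member peaks.
    """
    cell_tot = counts.sum(axis=0)
    frac = counts[member].sum() / counts.sum()
    expected = cell_tot * frac
    observed = counts[member].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (observed - expected) / expected
    return np.where(expected > 0, dev, 0.0)


def kmer_deviations(counts: np.ndarray, pk: PeakKmerMatrix,
                    n_background: int = 50, seed: int = 0,
                    cell_ids: list[str] | None = None,
                    n_bins: int = 10) -> DeviationMatrix:
    """Cells x k-mers accessibility deviation z-scores.

    For each k-mer, the raw deviation of its peak set is standardized
    against ``n_background`` random peak sets of the same size, sampled
    peak-for-peak from the same (mean accessibility, GC) bin; bins are
    decile grids over both coordinates. Deterministic given the seed.
    """
    counts = np.asarray(counts, float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.shape[0] != pk.matrix.shape[0]:
        raise ValueError("counts and k-mer matrix disagree on peak count")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(counts.shape[1])]
    cell_tot = counts.sum(axis=0)
    dead = np.flatnonzero(cell_tot == 0)
    if dead.size:
        warnings.warn(f"dropping {dead.size} cells with zero total reads")
        keep = np.flatnonzero(cell_tot > 0)
        counts = counts[:, keep]
        cell_ids = [cell_ids[i] for i in keep]

    n_peaks = counts.shape[0]
    mean_acc = counts.mean(axis=1)
    # decile bins on (mean accessibility, GC)
    acc_bin = np.searchsorted(
        np.quantile(mean_acc, np.linspace(0, 1, n_bins + 1)[1:-1]), mean_acc)
    gc_bin = np.searchsorted(
        np.quantile(pk.gc_content, np.linspace(0, 1, n_bins + 1)[1:-1]),
        pk.gc_content)
    bin_id = acc_bin * n_bins + gc_bin
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_id == b) for b in np.unique(bin_id)}

    rng = np.random.Generator(np.random.Philox(seed))
    n_cells, n_kmers = counts.shape[1], pk.matrix.shape[1]
    raw = np.zeros((n_cells, n_kmers))
    bg_mean = np.zeros((n_cells, n_kmers))
    bg_sd = np.zeros((n_cells, n_kmers))
    z = np.zeros((n_cells, n_kmers))
    total_reads = counts.sum()
    for j in range(n_kmers):
        member = pk.matrix[:, j].astype(bool)
        raw[:, j] = _deviation(counts, member)
        idx = np.flatnonzero(member)
        # matched sampling: each member peak is replaced by a random peak
        # from its (accessibility, GC) bin, n_background times at once
        sampled = np.empty((n_background, idx.size), dtype=int)
        for col_i, p in enumerate(idx):
            sampled[:, col_i] = rng.choice(bin_members[bin_id[p]],
                                           size=n_background)
        obs = counts[sampled.ravel()].reshape(
            n_background, idx.size, n_cells).sum(axis=1)
        frac = obs.sum(axis=1, keepdims=True) / total_reads
        expected = frac * counts.sum(axis=0)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            bg_devs = np.where(expected > 0,
                               (obs - expected) / expected, 0.0)
        bg_mean[:, j] = bg_devs.mean(axis=0)
        sd = bg_devs.std(axis=0, ddof=0)
        bg_sd[:, j] = sd
        with np.errstate(invalid="ignore", divide="ignore"):
            zj = (raw[:, j] - bg_mean[:, j]) / sd
        z[:, j] = np.where(sd > 0, zj, 0.0)
    return DeviationMatrix(zscores=z, raw=raw, kmers=list(pk.kmers),
                           cell_ids=list(cell_ids),
                           n_background=n_background,
                           background_mean=bg_mean, background_sd=bg_sd)


def atac_feature_prep(dev: DeviationMatrix, n_pcs: int = 15,
                      exclude_first: bool = True) -> np.ndarray:
    """Standardize k-mer z-scores and reduce to top PCs (dropping PC1).

    Returns a cells x n_pcs feature matrix ready for the MLLE embedding.
    """
    if not np.all(np.isfinite(dev.zscores)):
        raise ValueError("deviation matrix contains non-finite values")
    m = AnnotatedMatrix(values=dev.zscores.T,      # k-mers x cells
                        feature_names=list(dev.kmers),
                        cell_names=list(dev.cell_ids))
    return select_top_pcs(m, n_pcs=n_pcs, exclude_first=exclude_first)


def export_kmers_meme(kmers: list[str], path) -> None:
    """Write k-mers as a minimal MEME-format motif list for external annotation."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "strands: + -", ""]
    onehot = {"A": "1 0 0 0", "C": "0 1 0 0", "G": "0 0 1 0",
              "T": "0 0 0 1"}
    for km in kmers:
        lines += [f"MOTIF {km}",
                  f"letter-probability matrix: alength= 4 w= {len(km)}"]
        lines += [onehot[c] for c in km]
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
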