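"""Synthetic tree-structured data with known topology, pseudotime and markers.

The generator states a world and sticks to it: cells live on a known tree
of branches; every gene's mean expression drifts linearly along each
branch, continuous at branching nodes; i.i.d. Gaussian noise is added on
top. Genes come in four kinds:

* structure genes — random drift slopes on every branch; they carry the
  geometry the embedding has to recover;
* planted diverging markers — slope on one designated branch of a sibling
  pair, flat on the other;
* planted transition markers — a strong monotone slope along one branch;
* planted leaf markers — a slope only on one terminal branch;
* null genes — flat everywhere (noise only); false-positive accounting
  uses exactly these.

Values are generated directly on the post-normalization log scale.
Randomness uses the counter-based Philox generator, so a (spec, seed)
pair regenerates fixtures bit-identically across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AnnotatedMatrix
from .markers import BranchAnnotation

__all__ = ["BranchSpec", "SyntheticTruth", "make_tree_data",
           "make_toy_atac", "y_tree_fixture", "tri_timepoint_fixture"]

#: default effect size (log2 units) of planted markers — a 4-fold change,
#: typical of the marker genes reported for hematopoietic branch decisions
_EFFECT = 2.0


@dataclass(frozen=True)
class BranchSpec:
    name: str
    parent: str | None
    length: float = 1.0


@dataclass
class SyntheticTruth:
    branches: list[BranchSpec]
    cell_branch: np.ndarray           # branch name per cell
    cell_position: np.ndarray         # offset along own branch
    cell_pseudotime: np.ndarray       # distance from root start
    cell_label: list[str]             # T1/T2/... time-point label
    diverging_markers: list[tuple[str, tuple[str, str]]]
    transition_markers: list[tuple[str, str]]
    leaf_markers: list[tuple[str, str]]
    null_genes: list[str]
    seed: int

    def marker_genes(self) -> set[str]:
        return ({g for g, _ in self.diverging_markers}
                | {g for g, _ in self.transition_markers}
                | {g for g, _ in self.leaf_markers})

    def branch_children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {b.name: [] for b in self.branches}
        for b in self.branches:
            if b.parent is not None:
                ch[b.parent].append(b.name)
        return ch

    def leaf_branch_names(self) -> list[str]:
        ch = self.branch_children()
        leaves = [b.name for b in self.branches if not ch[b.name]]
        roots = [b.name for b in self.branches if b.parent is None]
        # the free end of the root branch is a terminal state too
        return sorted(set(leaves) | set(roots))

    def to_annotation(self) -> BranchAnnotation:
        """Ground-truth branch annotation in the detectors' input format."""
        states: dict[str, tuple[str, str]] = {}
        for b in self.branches:
            start = f"J_{b.parent}" if b.parent is not None else "J_root0"
            states[b.name] = (start, f"J_{b.name}")
        return BranchAnnotation(
            branch_ids=sorted(states),
            cell_branch=self.cell_branch.copy(),
            cell_pseudotime=self.cell_pseudotime.copy(),
            branch_states=states,
            leaf_branch_ids=self.leaf_branch_names(),
        )


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _sibling_pairs(branches: list[BranchSpec]) -> list[tuple[str, str]]:
    by_parent: dict[str, list[str]] = {}
    for b in branches:
        if b.parent is not None:
            by_parent.setdefault(b.parent, []).append(b.name)
    pairs = []
    for parent in sorted(by_parent):
        sibs = sorted(by_parent[parent])
        for i in range(len(sibs) - 1):
            pairs.append((sibs[i], sibs[i + 1]))
    return pairs


def make_tree_data(branches: list[BranchSpec], cells_per_branch: int = 100,
                   n_genes: int = 200, noise_sd: float = 0.3,
                   n_markers: int = 5, seed: int = 42,
                   drift_sd: float = 1.0, effect: float = _EFFECT,
                   null_fraction: float = 0.3,
                   ) -> tuple[AnnotatedMatrix, SyntheticTruth]:
    """Generate tree-structured expression data with planted markers.

    ``n_markers`` markers of each kind are planted (per sibling pair for
    diverging markers). ``null_fraction`` of the genes are flat null genes.
    """
    if noise_sd <= 0:
        # the noiseless limit is allowed for oracle tests
        noise_sd = max(noise_sd, 0.0)
    names = {b.name for b in branches}
    if len(names) != len(branches):
        raise ValueError("duplicate branch names")
    for b in branches:
        if b.parent is not None and b.parent not in names:
            raise ValueError(f"branch {b.name} has unknown parent {b.parent}")
        if b.length <= 0:
            raise ValueError("branch lengths must be positive")
    roots = [b for b in branches if b.parent is None]
    if len(roots) != 1:
        raise ValueError("topology must have exactly one root branch")

    rng = _rng(seed)
    by_name = {b.name: b for b in branches}

    # branch depth (pseudotime of branch start) and generation
    depth: dict[str, float] = {}
    gen: dict[str, int] = {}

    def _depth(name: str) -> float:
        if name in depth:
            return depth[name]
        b = by_name[name]
        if b.parent is None:
            depth[name] = 0.0
            gen[name] = 1
        else:
            depth[name] = _depth(b.parent) + by_name[b.parent].length
            gen[name] = gen[b.parent] + 1
        return depth[name]

    for b in branches:
        _depth(b.name)

    # gene roles
    sib_pairs = _sibling_pairs(branches)
    n_null = int(round(null_fraction * n_genes))
    n_div = n_markers * len(sib_pairs)
    leaf_names = [b.name for b in branches
                  if not any(c.parent == b.name for c in branches)]
    n_trans = n_markers
    n_leaf = n_markers if leaf_names else 0
    n_struct = n_genes - n_null - n_div - n_trans - n_leaf
    if n_struct < 10:
        raise ValueError("n_genes too small for the requested markers")
    gene_names = [f"g{i:04d}" for i in range(n_genes)]

    # slopes: genes x branches
    branch_order = [b.name for b in branches]
    col = {name: i for i, name in enumerate(branch_order)}
    slopes = np.zeros((n_genes, len(branches)))
    gi = 0
    struct_idx = range(gi, gi + n_struct)
    for i in struct_idx:
        slopes[i] = rng.normal(0.0, drift_sd, size=len(branches))
    gi += n_struct

    diverging_markers = []
    for pa, pb in sib_pairs:
        for m in range(n_markers):
            up = pa if m % 2 == 0 else pb      # alternate the favored branch
            slopes[gi, col[up]] = effect / by_name[up].length
            diverging_markers.append((gene_names[gi], (pa, pb)))
            gi += 1

    transition_markers = []
    trans_branch = max(branch_order, key=lambda nm: by_name[nm].length)
    for m in range(n_trans):
        slopes[gi, col[trans_branch]] = effect / by_name[trans_branch].length
        transition_markers.append((gene_names[gi], trans_branch))
        gi += 1

    leaf_markers = []
    for m in range(n_leaf):
        lb = leaf_names[m % len(leaf_names)]
        slopes[gi, col[lb]] = effect / by_name[lb].length
        leaf_markers.append((gene_names[gi], lb))
        gi += 1

    null_genes = gene_names[gi:]

    # branch-start mean vectors by continuity
    base = rng.normal(2.0, 0.5, size=n_genes)
    start_mean: dict[str, np.ndarray] = {}

    def _start(name: str) -> np.ndarray:
        if name in start_mean:
            return start_mean[name]
        b = by_name[name]
        if b.parent is None:
            start_mean[name] = base.copy()
        else:
            p = by_name[b.parent]
            start_mean[name] = _start(p.name) + slopes[:, col[p.name]] * p.length
        return start_mean[name]

    for b in branches:
        _start(b.name)

    # cells
    cell_branch, cell_pos, cell_pt, cell_label = [], [], [], []
    cols = []
    for b in branches:
        pos = np.sort(rng.uniform(0.0, b.length, size=cells_per_branch))
        mu = (start_mean[b.name][:, None]
              + slopes[:, col[b.name]][:, None] * pos[None, :])
        cols.append(mu)
        cell_branch += [b.name] * cells_per_branch
        cell_pos.append(pos)
        cell_pt.append(depth[b.name] + pos)
        cell_label += [f"T{gen[b.name]}"] * cells_per_branch
    values = np.concatenate(cols, axis=1)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    n_cells = values.shape[1]
    matrix = AnnotatedMatrix(
        values=values,
        feature_names=gene_names,
        cell_names=[f"c{i:04d}" for i in range(n_cells)],
        cell_labels=cell_label,
        normalized=True, log_transformed=True,
    )
    truth = SyntheticTruth(
        branches=list(branches),
        cell_branch=np.array(cell_branch),
        cell_position=np.concatenate(cell_pos),
        cell_pseudotime=np.concatenate(cell_pt),
        cell_label=cell_label,
        diverging_markers=diverging_markers,
        transition_markers=transition_markers,
        leaf_markers=leaf_markers,
        null_genes=list(null_genes),
        seed=seed,
    )
    return matrix, truth


def y_tree_fixture(seed: int = 42, cells_per_branch: int = 100,
                   n_genes: int = 200, noise_sd: float = 0.3,
                   n_markers: int = 5):
    """One bifurcation: a root branch splitting into two arms of unit length."""
    branches = [
        BranchSpec("root", None, 1.0),
        BranchSpec("armA", "root", 1.0),
        BranchSpec("armB", "root", 1.0),
    ]
    return make_tree_data(branches, cells_per_branch=cells_per_branch,
                          n_genes=n_genes, noise_sd=noise_sd,
                          n_markers=n_markers, seed=seed)


def tri_timepoint_fixture(seed: int = 42, cells_per_branch: int = 150,
                          n_genes: int = 200, noise_sd: float = 0.3):
    """Two nested bifurcations with three time-point labels (T1/T2/T3).

    The first bifurcation separates T1 from T2, the second splits one T2
    arm into two T3 fates; 150 cells per branch, 200 genes, noise 0.3.
    """
    branches = [
        BranchSpec("root", None, 1.0),
        BranchSpec("armA", "root", 1.0),
        BranchSpec("armB", "root", 1.0),
        BranchSpec("armA1", "armA", 1.0),
        BranchSpec("armA2", "armA", 1.0),
    ]
    return make_tree_data(branches, cells_per_branch=cells_per_branch,
                          n_genes=n_genes, noise_sd=noise_sd, seed=seed)


_BASES = np.array(list("ACGT"))


def make_toy_atac(n_peaks: int = 200, n_cells: int = 200, k: int = 7,
                  planted_kmer: str = "GATTACA", enrichment: float = 2.0,
                  seed: int = 0, peak_length: int = 50,
                  planted_fraction: float = 0.2):
    """Toy peak-count data with one k-mer enriched in one cell group.

    Random peak sequences; the planted k-mer is inserted into a fixed
    fraction of peaks; Poisson fragment counts whose rate is multiplied by
    ``enrichment`` for planted peaks in the second half of the cells (the
    designated group G).
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if len(planted_kmer) > peak_length:
        raise ValueError("planted k-mer longer than the peak length")
    rng = _rng(seed)
    seqs = ["".join(rng.choice(_BASES, size=peak_length))
            for _ in range(n_peaks)]
    n_planted = max(1, int(round(planted_fraction * n_peaks)))
    planted_peaks = np.sort(rng.choice(n_peaks, size=n_planted,
                                       replace=False))
    for p in planted_peaks:
        pos = int(rng.integers(0, peak_length - len(planted_kmer) + 1))
        s = seqs[p]
        seqs[p] = s[:pos] + planted_kmer + s[pos + len(planted_kmer):]

    base_rate = rng.uniform(1.0, 3.0, size=n_peaks)
    group = np.zeros(n_cells, dtype=bool)
    group[n_cells // 2:] = True
    rates = np.tile(base_rate[:, None], (1, n_cells))
    rates[np.ix_(planted_peaks, np.flatnonzero(group))] *= enrichment
    counts = rng.poisson(rates).astype(float)
    truth = {
        "group": group,
        "planted_peaks": planted_peaks,
        "planted_kmer": planted_kmer,
        "seed": seed,
    }
    peak_ids = [f"peak{i:04d}" for i in range(n_peaks)]
    return counts, seqs, peak_ids, truth
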