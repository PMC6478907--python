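"""End-to-end trajectory pipeline chaining all stages with one config.

``run_pipeline`` takes a features x cells matrix and executes: optional
normalization + variable-feature selection (skipped for matrices already
on the log scale), MLLE embedding, exemplar + MST seeding, elastic-tree
growth, the four refinement rules, branch extraction, cell projection and
pseudotime, and (optionally) the three marker detectors. Everything is
driven by a :class:`~elastree.data_model.RunConfig` and a single seed; two
runs with the same config and input produce identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import AnnotatedMatrix, RunConfig
from .epg import ElasticParams, PrincipalGraph, grow_tree
from .markers import (BranchAnnotation, detect_diverging, detect_leaf,
                      detect_transition)
from .mlle import Embedding, fit_mlle
from .preprocess import normalize_and_log, select_variable_genes, \
    subset_features
from .refine import RefineParams, refine_tree
from .seeding import SeedGraph, seed_high_dim, seed_tree
from .tree_coords import (BranchSet, CellProjection, default_root,
                          extract_branches, project_cells, pseudotime)

__all__ = ["PipelineResult", "run_pipeline", "choose_root"]


@dataclass
class PipelineResult:
    matrix: AnnotatedMatrix
    embedding: Embedding
    seed_graph: SeedGraph
    tree: PrincipalGraph
    branch_set: BranchSet
    projections: list[CellProjection]
    root_state: str
    pseudotime: np.ndarray
    annotation: BranchAnnotation
    markers: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def choose_root(branch_set: BranchSet, projections, cell_labels) -> str:
    """Leaf state whose branch is most enriched for the earliest label.

    Labels are ordered by sorted unique name (T1 < T2 < ...); the leaf
    branch with the lowest mean label rank marks the starting population,
    and its terminal state is the root. Falls back to the longest-path
    leaf without labels.
    """
    if cell_labels is None:
        return default_root(branch_set)
    ranks = {lab: i for i, lab in enumerate(sorted(set(cell_labels)))}
    deg = branch_set.state_degrees()
    cell_branch = [p.branch_id for p in projections]
    best_state, best_rank = None, np.inf
    for bid in branch_set.leaf_branches(deg):
        b = branch_set.branches[bid]
        cells = [i for i, cb in enumerate(cell_branch) if cb == bid]
        if not cells:
            continue
        mean_rank = float(np.mean([ranks[cell_labels[i]] for i in cells]))
        if mean_rank < best_rank:
            best_rank = mean_rank
            # terminal (degree-1) endpoint of the leaf branch
            s0, s1 = b.states
            best_state = s0 if deg[s0] == 1 else s1
    return best_state if best_state is not None else default_root(branch_set)


def run_pipeline(m: AnnotatedMatrix, config: RunConfig | None = None,
                 feature_selection: str = "auto",
                 root_state: Optional[str] = None,
                 seed_dims: Optional[int] = None,
                 detect_markers: bool = False) -> PipelineResult:
    """Run the full trajectory pipeline on a features x cells matrix.

    ``feature_selection``: "loess" (variable genes), "none" (use all
    features), or "auto" — loess for raw count matrices (which are then
    normalized and log-transformed first), all features for matrices
    already flagged normalized/log-transformed, as synthetic fixtures are.
    """
    if config is None:
        config = RunConfig()
    manifest: dict = {"stages": [], "seed": config.random_seed}

    if feature_selection == "auto":
        feature_selection = "none" if (m.normalized or m.log_transformed) \
            else "loess"
    if not (m.normalized or m.log_transformed):
        m = normalize_and_log(m)
        manifest["stages"].append("normalize_and_log")
    if feature_selection == "loess":
        vg = select_variable_genes(
            m, loess_fraction=config.loess_fraction,
            residual_cutoff_percentile=config.residual_cutoff_percentile)
        selected = subset_features(m, vg)
        if selected.n_features >= 10:
            m = selected
        manifest["stages"].append(
            f"select_variable_genes({m.n_features} kept)")

    emb = fit_mlle(m.values.T, d=config.mlle_components,
                   neighbor_fraction=config.mlle_neighbor_fraction)
    manifest["stages"].append(f"fit_mlle(d={emb.d}, k={emb.n_neighbors})")

    ep = ElasticParams(R0=config.epg_trimming_radius,
                       lam=config.epg_lambda, mu=config.epg_mu,
                       alpha=config.epg_alpha,
                       n_nodes_target=config.epg_n_nodes)
    if seed_dims is not None and seed_dims < emb.d:
        def _fit_low(low):
            sg = seed_tree(low, damping=config.ap_damping,
                           random_seed=config.random_seed)
            g = grow_tree(low, sg, ElasticParams(
                R0=ep.R0, lam=ep.lam, mu=ep.mu, alpha=ep.alpha,
                n_nodes_target=ep.n_nodes_target))
            return g.node_coords, g.edges
        sg = seed_high_dim(emb.coords, L=seed_dims,
                           damping=config.ap_damping,
                           random_seed=config.random_seed,
                           fit_low_dim=_fit_low)
    else:
        sg = seed_tree(emb.coords, damping=config.ap_damping,
                       random_seed=config.random_seed)
    manifest["stages"].append(f"seed_tree({sg.n_nodes} nodes)")

    tree = grow_tree(emb.coords, sg, ep)
    manifest["stages"].append(f"grow_tree({tree.n_nodes} nodes)")

    rp = RefineParams(min_branch_cells=config.min_branch_cells,
                      min_branch_length_frac=config.min_branch_length_frac,
                      finetune_n_nodes=config.finetune_n_nodes,
                      extend_percentile=config.extend_percentile)
    tree = refine_tree(tree, emb.coords, rp, ep)
    manifest["stages"].append(f"refine_tree({tree.n_nodes} nodes)")

    branch_set = extract_branches(tree)
    projections = project_cells(tree, emb.coords, branch_set,
                                random_seed=config.random_seed)
    if root_state is None:
        root_state = choose_root(branch_set, projections, m.cell_labels)
    pt = pseudotime(tree, projections, root_state, branch_set)
    manifest["stages"].append(f"pseudotime(root={root_state})")

    ann = BranchAnnotation.from_tree(branch_set, projections, pt)
    markers: dict = {}
    if detect_markers:
        markers["diverging"] = detect_diverging(
            m.values, m.feature_names, ann,
            fc_threshold=config.fc_threshold,
            z_threshold=config.z_threshold)
        markers["transition"] = detect_transition(
            m.values, m.feature_names, ann,
            fc_threshold=config.fc_threshold,
            rho_threshold=config.rho_threshold)
        if len(ann.leaf_branch_ids) >= 3:
            markers["leaf"] = detect_leaf(
                m.values, m.feature_names, ann,
                z_cut=config.leaf_z_cut, p_cut=config.leaf_p_cut)
        manifest["stages"].append("detect_markers")

    return PipelineResult(matrix=m, embedding=emb, seed_graph=sg,
                          tree=tree, branch_set=branch_set,
                          projections=projections, root_state=root_state,
                          pseudotime=pt, annotation=ann, markers=markers,
                          manifest=manifest)
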