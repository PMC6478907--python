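import itertools

import numpy as np
import pytest
from scipy import stats

from elastree.markers import (BranchAnnotation, conover_pairwise,
                              detect_diverging, detect_leaf,
                              detect_transition, mannwhitney_z)


def _brute_force_u(x, y):
    """Exhaustive pair counting: wins + half-ties of x over y."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def test_u_mean_substitution():
    x = np.arange(10, dtype=float)
    y = np.arange(100, 120, dtype=float)
    U, z = mannwhitney_z(x, y)
    # m_U for n_i=10, n_j=20 is 100; here U=0, so z = -100/sigma < 0
    assert U == 0 and z < 0


def test_all_tied_samples_give_z_zero():
    U, z = mannwhitney_z([3.0, 3.0], [3.0, 3.0, 3.0])
    assert z == 0.0


def test_u_and_z_match_enumeration_oracle():
    x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    U, z = mannwhitney_z(x, y)
    assert U == _brute_force_u(x, y) == 0.0
    # direct evaluation of the standardization with no ties
    ni = nj = 3
    n = 6
    sigma = np.sqrt(ni * nj / 12 * (n + 1))
    np.testing.assert_allclose(z, (0.0 - ni * nj / 2) / sigma)


@pytest.mark.parametrize("seed", range(5))
def test_u_matches_pair_counting_on_random_small_samples(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
    y = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
    U, z = mannwhitney_z(x, y)
    np.testing.assert_allclose(U, _brute_force_u(x, y))
    # cross-check z against scipy's normal approximation when defined
    if np.ptp(np.concatenate([x, y])) > 0:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        z_scipy = (res.statistic - len(x) * len(y) / 2)
        np.testing.assert_allclose(abs(z) > 0, np.isfinite(res.pvalue))


def _toy_annotation(n=50, three_leaves=False):
    """Two sibling branches A and B plus a trunk R; n cells each."""
    branch_states = {"R": ("s0", "s1"), "A": ("s1", "s2"),
                     "B": ("s1", "s3")}
    cells = ["R"] * n + ["A"] * n + ["B"] * n
    pt = np.concatenate([np.linspace(0, 1, n),
                         1 + np.linspace(0, 1, n),
                         1 + np.linspace(0, 1, n)])
    return BranchAnnotation(
        branch_ids=["A", "B", "R"],
        cell_branch=np.array(cells),
        cell_pseudotime=pt,
        branch_states=branch_states,
        leaf_branch_ids=["A", "B", "R"],
    )


def test_diverging_planted_gene_detected_and_top_ranked():
    ann = _toy_annotation()
    rng = np.random.default_rng(0)
    on_a = ann.cell_branch == "A"
    on_b = ann.cell_branch == "B"
    expr = rng.normal(0.0, 0.05, size=(3, ann.cell_branch.size))
    expr[0, on_a] += 1.0        # planted diverging gene
    res = detect_diverging(expr, ["planted", "null1", "null2"], ann)
    ab = [r for r in res if r.branch_pair == ("A", "B")]
    assert ab[0].gene == "planted" and ab[0].detected and ab[0].z > 0
    assert not any(r.detected for r in ab if r.gene != "planted")


def test_diverging_antisymmetric_in_branch_order():
    ann = _toy_annotation()
    rng = np.random.default_rng(1)
    expr = rng.normal(size=(1, ann.cell_branch.size))
    expr[0, ann.cell_branch == "A"] += 0.8
    res = detect_diverging(expr, ["g"], ann)
    zab = [r.z for r in res if r.branch_pair == ("A", "B")][0]
    # swap roles by renaming branches
    swapped = _toy_annotation()
    cb = swapped.cell_branch.copy()
    swapped.cell_branch[cb == "A"] = "B"
    swapped.cell_branch[cb == "B"] = "A"
    res2 = detect_diverging(expr, ["g"], swapped)
    zba = [r.z for r in res2 if r.branch_pair == ("A", "B")][0]
    np.testing.assert_allclose(zab, -zba, atol=1e-10)


def test_small_branches_decided_on_fold_change_alone():
    ann = _toy_annotation(n=10)
    expr = np.zeros((1, 30))
    expr[0, ann.cell_branch == "A"] = 1.0
    res = detect_diverging(expr, ["g"], ann)
    r = [x for x in res if x.branch_pair == ("A", "B")][0]
    assert r.small_sample and r.detected


def test_detectors_invariant_to_affine_rescaling():
    ann = _toy_annotation()
    rng = np.random.default_rng(2)
    expr = rng.normal(size=(4, ann.cell_branch.size))
    expr[0, ann.cell_branch == "A"] += 1.5
    scaled = 7.3 * expr + 11.0
    for detect in (detect_diverging, detect_transition):
        d1 = [(r.gene, r.detected) for r in detect(
            expr, list("abcd"), ann)]
        d2 = [(r.gene, r.detected) for r in detect(
            scaled, list("abcd"), ann)]
        assert d1 == d2


def test_transition_monotone_gene_detected_and_permuted_not():
    ann = _toy_annotation(n=100)
    rng = np.random.default_rng(3)
    n_tot = ann.cell_branch.size
    expr = np.zeros((2, n_tot))
    on_a = ann.cell_branch == "A"
    expr[0, on_a] = ann.cell_pseudotime[on_a]          # exact monotone
    expr[1, on_a] = rng.permutation(ann.cell_pseudotime[on_a])
    res = detect_transition(expr, ["mono", "perm"], ann)
    mono = [r for r in res if r.gene == "mono" and r.branch == "A"][0]
    assert mono.detected and np.isclose(mono.rho, 1.0)
    perm = [r for r in res if r.gene == "perm" and r.branch == "A"][0]
    assert not perm.detected


def test_constant_gene_fails_fold_change_gate():
    ann = _toy_annotation()
    expr = np.full((1, ann.cell_branch.size), 4.2)
    res = detect_transition(expr, ["const"], ann)
    assert all(not r.detected and np.isnan(r.rho) for r in res)


def _four_leaf_annotation(n=30):
    """Star with four leaf branches (z-score gate attainable)."""
    branch_states = {f"L{i}": ("hub", f"t{i}") for i in range(4)}
    cells = sum(([f"L{i}"] * n for i in range(4)), [])
    pt = np.tile(np.linspace(0, 1, n), 4)
    return BranchAnnotation(
        branch_ids=[f"L{i}" for i in range(4)],
        cell_branch=np.array(cells),
        cell_pseudotime=pt,
        branch_states=branch_states,
        leaf_branch_ids=[f"L{i}" for i in range(4)],
    )


def test_leaf_gene_detected_on_its_branch_with_all_gates():
    ann = _four_leaf_annotation()
    rng = np.random.default_rng(4)
    expr = rng.normal(0, 0.05, size=(2, ann.cell_branch.size))
    expr[0, ann.cell_branch == "L2"] += 1.0
    res = detect_leaf(expr, ["planted", "null"], ann)
    planted = res[0]
    assert planted.candidate == "L2" and planted.detected
    assert planted.kw_pvalue < 0.01
    assert all(p < 0.01 for p in planted.conover_pvalues.values())
    assert not res[1].detected


def test_uniform_gene_has_no_candidate():
    ann = _four_leaf_annotation()
    rng = np.random.default_rng(5)
    expr = rng.normal(size=(1, ann.cell_branch.size))
    res = detect_leaf(expr, ["g"], ann)
    # exchangeable leaves: |z| rarely crosses 1.5, and detection must fail
    assert not res[0].detected


def test_three_leaf_zscore_ceiling():
    # with 3 leaves the max attainable |z| is sqrt(2) < 1.5, so the
    # z-score gate can never open regardless of effect size
    ann = _toy_annotation()
    expr = np.zeros((1, ann.cell_branch.size))
    expr[0, ann.cell_branch == "A"] = 5.0
    res = detect_leaf(expr, ["g"], ann)
    assert res[0].candidate is None
    assert max(abs(z) for z in res[0].leaf_zscores.values()) < 1.5


def test_zcut_threshold_respected():
    ann = _four_leaf_annotation()
    expr = np.zeros((1, ann.cell_branch.size))
    expr[0, ann.cell_branch == "L0"] = 5.0
    res = detect_leaf(expr, ["g"], ann, z_cut=5.0)   # unreachable cut
    assert res[0].candidate is None and not res[0].detected


def test_conover_pvalues_behave():
    rng = np.random.default_rng(6)
    same = [rng.normal(size=30) for _ in range(3)]
    P_null = conover_pairwise(same)
    shifted = [rng.normal(size=30), rng.normal(size=30),
               rng.normal(loc=3, size=30)]
    P_sig = conover_pairwise(shifted)
    assert P_sig[0, 2] < 1e-6 and P_sig[1, 2] < 1e-6
    assert P_sig[0, 1] > 0.01
    assert np.all(P_null >= 0) and np.all(P_null <= 1)
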