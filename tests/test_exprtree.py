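"""Expression distance matrices, neighbour joining, RF distance and the
divergence–time statistics."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from sbgevo import exprtree
from sbgevo.simulate import SimulationConfig, simulate_tree


def tree_from_newick(nwk: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=nwk, schema="newick")
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# 1 - rho distances

def test_spearman_distance_worked_values():
    prof = pd.DataFrame({"a": [1, 2, 3], "b": [3, 1, 2], "c": [1, 2, 3],
                         "d": [3, 2, 1]})
    d = exprtree.spearman_distance_matrix(prof)
    assert d.loc["a", "b"] == pytest.approx(1.5)   # rho = -0.5
    assert d.loc["a", "c"] == 0.0                  # identical
    assert d.loc["a", "d"] == pytest.approx(2.0)   # reversed ranks
    assert np.allclose(d, d.T) and (d.values <= 2 + 1e-12).all()


def test_spearman_distance_constant_profile_raises():
    prof = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]})
    with pytest.raises(ValueError, match="b"):
        exprtree.spearman_distance_matrix(prof)


# ---------------------------------------------------------------------------
# neighbour joining

def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(D, index=[t.label for t in taxa],
                        columns=[t.label for t in taxa])


def test_nj_three_taxa_exact():
    # distances d(ab)=3, d(ac)=4, d(bc)=5 -> a=1, b=2, c=3
    D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                     index=list("abc"), columns=list("abc"))
    tree = exprtree.nj_tree(D)
    lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lens == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


def test_nj_zero_length_cherry_for_identical_rows():
    D = pd.DataFrame([[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]],
                     index=list("abcd"), columns=list("abcd"), dtype=float)
    tree = exprtree.nj_tree(D)
    ab = [l for l in tree.leaf_node_iter() if l.taxon.label in "ab"]
    assert ab[0].parent_node is ab[1].parent_node
    assert all(l.edge.length == pytest.approx(0.0) for l in ab)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_nj_recovers_additive_matrices(seed):
    """On patristic distances of a random tree (n<=5), NJ must recover the
    generating topology and branch lengths exactly."""
    cfg = SimulationConfig(seed=seed, n_species=5)
    true_tree = simulate_tree(cfg)
    D = _patristic(true_tree)
    est = exprtree.nj_tree(D)
    rf, _ = exprtree.rf_distance(est, true_tree)
    assert rf == 0
    D_est = _patristic(est)
    assert np.allclose(D_est.loc[D.index, D.columns], D, atol=1e-9)


def test_nj_matches_scikit_bio_topology():
    """Cross-check against an independent NJ implementation."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    n = 6
    labels = [f"t{i}" for i in range(n)]
    base = rng.random((n, 3))
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = np.abs(base[i] - base[j]).sum()
    ours = exprtree.nj_tree(pd.DataFrame(D, index=labels, columns=labels))
    import io as _io
    dm = skbio.DistanceMatrix(D, ids=labels)
    buf = _io.StringIO()
    skbio.tree.nj(dm).write(buf, format="newick")
    theirs = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    rf, _ = exprtree.rf_distance(ours, theirs)
    assert rf == 0


def test_nj_rejects_bad_input():
    D = pd.DataFrame([[0, np.inf], [np.inf, 0]], index=list("ab"),
                     columns=list("ab"))
    with pytest.raises(ValueError, match="finite"):
        exprtree.nj_tree(D)


# ---------------------------------------------------------------------------
# Robinson-Foulds

def test_rf_identical_topologies_zero(balanced_four_taxon_tree):
    other = tree_from_newick("((A:2,B:2):2,(C:9,D:1):1);")
    rf, norm = exprtree.rf_distance(balanced_four_taxon_tree, other)
    assert rf == 0 and norm == 0.0


def test_rf_four_taxon_conflict_and_star(balanced_four_taxon_tree):
    conflict = tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    rf, norm = exprtree.rf_distance(balanced_four_taxon_tree, conflict)
    assert rf == 2 and norm == 1.0
    star = tree_from_newick("(A:1,B:1,C:1,D:1);")
    rf_s, norm_s = exprtree.rf_distance(balanced_four_taxon_tree, star)
    assert rf_s == 1 and norm_s == 1.0


def test_rf_is_metric_on_random_trees():
    trees = []
    for seed in (0, 1, 2):
        trees.append(simulate_tree(SimulationConfig(seed=seed, n_species=7)))
    for a, b in itertools.combinations(trees, 2):
        rf_ab, _ = exprtree.rf_distance(a, b)
        rf_ba, _ = exprtree.rf_distance(b, a)
        assert rf_ab == rf_ba
    for t in trees:
        assert exprtree.rf_distance(t, t)[0] == 0
    abc = [exprtree.rf_distance(a, b)[0]
           for a, b in itertools.combinations(trees, 2)]
    assert abc[0] <= abc[1] + abc[2]


def test_rf_tip_mismatch_raises(balanced_four_taxon_tree):
    other = tree_from_newick("((A:1,B:1):1,(C:1,E:1):1);")
    with pytest.raises(ValueError, match="E"):
        exprtree.rf_distance(balanced_four_taxon_tree, other)


# ---------------------------------------------------------------------------
# rooting and root-to-tip lengths

def test_root_to_tip_path_sums():
    t = tree_from_newick("((A:1,B:2):1,C:2);")
    out = exprtree.root_to_tip_lengths(t)
    assert out.to_dict() == pytest.approx({"A": 2.0, "B": 3.0, "C": 2.0})


def test_root_to_tip_scaling_linearity():
    t = tree_from_newick("((A:1,B:2):1,C:2);")
    base = exprtree.root_to_tip_lengths(t)
    for e in t.preorder_edge_iter():
        if e.length:
            e.length *= 3.0
    assert np.allclose(exprtree.root_to_tip_lengths(t), 3 * base)


def test_root_tree_outgroup_and_midpoint():
    t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:3):1);", schema="newick")
    rooted = exprtree.root_tree(t, outgroup="A")
    # A sits adjacent to the root after outgroup rooting
    a = next(l for l in rooted.leaf_node_iter() if l.taxon.label == "A")
    assert a.parent_node is rooted.seed_node or \
        a.parent_node.parent_node is rooted.seed_node
    mid = exprtree.root_tree(t, outgroup=None)
    assert mid.is_rooted


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_supports_reproducible_and_order_invariant(rng):
    genes = [f"g{i}" for i in range(60)]
    prof = pd.DataFrame(rng.lognormal(3, 1, size=(60, 5)), index=genes,
                        columns=list("abcde"))
    t1 = exprtree.bootstrap_supports(prof, n_boot=30, seed=9)
    t2 = exprtree.bootstrap_supports(prof, n_boot=30, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    shuffled = prof.sample(frac=1.0, random_state=1)
    t3 = exprtree.bootstrap_supports(shuffled, n_boot=30, seed=9)
    labels = sorted(n.label for n in t1.preorder_node_iter() if n.label)
    labels3 = sorted(n.label for n in t3.preorder_node_iter() if n.label)
    assert len(labels) == len(labels3)


def test_bootstrap_strong_signal_high_support(rng):
    """Profiles generated on a clean additive structure: true splits get
    near-full support."""
    cfg = SimulationConfig(seed=2, n_species=5)
    tree = simulate_tree(cfg)
    from sbgevo.ancestral import brownian_covariance
    sp = sorted(t.taxon.label for t in tree.leaf_node_iter())
    C = brownian_covariance(tree, sp)
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(sp)))
    z = rng.standard_normal((4000, len(sp))) @ L.T
    prof = pd.DataFrame(z + rng.normal(5, 3, 4000)[:, None], columns=sp)
    bt = exprtree.bootstrap_supports(prof, n_boot=50, seed=3)
    supports = [float(n.label) for n in bt.preorder_node_iter() if n.label]
    assert supports and min(supports) >= 0.9


# ---------------------------------------------------------------------------
# divergence-time statistics

def test_expression_rate():
    assert exprtree.expression_rate(1.0, 5.0) == 0.0
    assert exprtree.expression_rate(0.9, 5.0) == pytest.approx(0.02)
    assert math.isnan(exprtree.expression_rate(0.5, 0.0))
    assert exprtree.expression_rate(0.5, 2.0) > exprtree.expression_rate(0.8, 2.0)


def test_divergence_regression_decays_under_brownian_motion(rng):
    cfg = SimulationConfig(seed=6, n_species=8)
    tree = simulate_tree(cfg)
    from sbgevo.ancestral import brownian_covariance
    sp = sorted(t.taxon.label for t in tree.leaf_node_iter())
    C = brownian_covariance(tree, sp)
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(sp)))
    neg = 0
    for rep in range(10):
        z = rng.standard_normal((800, len(sp))) @ L.T * 0.6
        prof = pd.DataFrame(z + rng.normal(5, 2, 800)[:, None], columns=sp)
        reg = exprtree.divergence_regression(prof, tree)
        neg += reg["slope"] < 0
    assert neg >= 9


def test_per_lg_correlation_and_exclusions(rng):
    genes = [f"g{i}" for i in range(30)]
    prof = pd.DataFrame(rng.lognormal(3, 1, (30, 4)), index=genes,
                        columns=list("abcd"))
    lg = pd.Series(["LG1"] * 15 + ["LG2"] * 13 + ["LG3"] * 2, index=genes)
    table, test = exprtree.per_lg_correlation(prof, lg)
    assert set(table["lg"]) == {"LG1", "LG2"}  # LG3 too small, excluded
    assert test["n_lgs"] == 2 and np.isfinite(test["H"])
    single, test1 = exprtree.per_lg_correlation(prof, pd.Series("LG1", index=genes))
    assert math.isnan(test1["H"])
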