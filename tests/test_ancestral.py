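"""Mk model likelihood, joint reconstruction, turnover counting and PGLS,
checked against exhaustive enumeration on small trees."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from sbgevo import ancestral
from sbgevo.ancestral import (STATES, MkModelFit, brownian_covariance,
                              count_turnovers, fit_mk_equal_rates,
                              joint_ancestral_states, transition_matrix)
from sbgevo.simulate import SimulationConfig, simulate_bias_states, simulate_tree


def tree_from_newick(nwk):
    t = dendropy.Tree.get(data=nwk, schema="newick")
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# brute-force oracles

def enumerate_likelihood(tree, tip_states, q):
    """Total likelihood by summing over every internal-state assignment."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = tip_states[leaf.taxon.label]
        prob = 1.0 / 3.0  # uniform root prior
        ok = True
        for n in nodes:
            if n.parent_node is None:
                continue
            s_par = assign[id(n.parent_node)]
            s_own = assign[id(n)]
            if s_own is None:  # missing tip: sum over its states = 1
                continue
            prob *= transition_matrix(q, n.edge.length or 0.0)[s_par, s_own]
        total += prob
    return total


def enumerate_best_joint(tree, tip_states, q):
    """Max-probability internal assignment by enumeration; returns the max
    joint probability (tie handling left to the implementation)."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = -1.0
    for combo in itertools.product(range(3), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = tip_states[leaf.taxon.label]
        prob = 1.0 / 3.0
        for n in nodes:
            if n.parent_node is None or assign[id(n)] is None:
                continue
            prob *= transition_matrix(q, n.edge.length or 0.0)[
                assign[id(n.parent_node)], assign[id(n)]]
        best = max(best, prob)
    return best


def joint_probability(tree, tip_states, node_states, q):
    nodes = list(tree.postorder_node_iter())
    assign = {}
    for n in nodes:
        if n.is_leaf():
            assign[id(n)] = tip_states[n.taxon.label]
        else:
            assign[id(n)] = node_states[n]
    prob = 1.0 / 3.0
    for n in nodes:
        if n.parent_node is None or assign[id(n)] is None:
            continue
        prob *= transition_matrix(q, n.edge.length or 0.0)[
            assign[id(n.parent_node)], assign[id(n)]]
    return prob


@pytest.mark.parametrize("nwk,states,q", [
    ("((A:1,B:1):1,C:2);", {"A": 2, "B": 0, "C": 1}, 0.3),
    ("((A:1,B:2):0.5,(C:1,D:1):1.5);", {"A": 2, "B": 2, "C": 0, "D": 1}, 0.7),
    ("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:1):1);",
     {"A": 2, "B": 2, "C": 0, "D": 0, "E": 1, "F": None}, 0.4),
])
def test_pruning_likelihood_matches_enumeration(nwk, states, q):
    tree = tree_from_newick(nwk)
    df = pd.DataFrame({sp: [STATES[s] if s is not None else np.nan]
                       for sp, s in states.items()})
    fit_like = ancestral._pruning_loglik(
        q, ancestral._TreeIndex(tree),
        {sp: ancestral._state_codes(df[[sp]]).ravel() for sp in states}, 1)
    brute = enumerate_likelihood(tree, states, q)
    assert fit_like == pytest.approx(math.log(brute), abs=1e-10)


@pytest.mark.parametrize("nwk,states,q", [
    ("((A:1,B:1):1,C:2);", {"A": 2, "B": 2, "C": 0}, 0.2),
    ("((A:1,B:2):0.5,(C:1,D:1):1.5);", {"A": 2, "B": 1, "C": 0, "D": 2}, 0.6),
    ("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:1):1);",
     {"A": 2, "B": 2, "C": 2, "D": 0, "E": 0, "F": 1}, 0.35),
])
def test_joint_reconstruction_matches_enumeration(nwk, states, q):
    tree = tree_from_newick(nwk)
    df = pd.DataFrame({sp: [STATES[s]] for sp, s in states.items()})
    nodes = joint_ancestral_states(df, tree, MkModelFit(q, 0.0, True))
    node_assign = {}
    ti = ancestral._TreeIndex(tree)
    for i, n in enumerate(ti.nodes):
        if not ti.is_leaf[i]:
            node_assign[n] = STATES.index(nodes[ti.labels[i]].iloc[0])
    ours = joint_probability(tree, states, node_assign, q)
    best = enumerate_best_joint(tree, states, q)
    assert ours == pytest.approx(best, rel=1e-10)


def test_joint_unanimous_tips_and_root_majority():
    tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    all_mbg = pd.DataFrame({sp: ["MBG"] for sp in "ABCD"})
    fit = MkModelFit(0.2, 0.0, True)
    nodes = joint_ancestral_states(all_mbg, tree, fit)
    assert (nodes.iloc[0] == "MBG").all()
    # 3 MBG vs 1 U at small q: root reconstructed MBG
    mixed = pd.DataFrame({"A": ["MBG"], "B": ["MBG"], "C": ["MBG"], "D": ["U"]})
    nodes = joint_ancestral_states(mixed, tree, MkModelFit(0.05, 0.0, True))
    root_label = nodes.columns[-1]
    assert nodes[root_label].iloc[0] == "MBG"


def test_joint_high_rate_ties_break_toward_U():
    tree = tree_from_newick("((A:1,B:1):1,C:2);")
    states = pd.DataFrame({"A": ["MBG"], "B": ["FBG"], "C": ["MBG"]})
    nodes = joint_ancestral_states(states, tree, MkModelFit(1e3, 0.0, True))
    # at q -> inf all assignments have equal probability: tie rule applies
    assert set(nodes.iloc[0]) == {"U"}


# ---------------------------------------------------------------------------
# rate fitting

def test_fit_monomorphic_boundary():
    tree = tree_from_newick("((A:1,B:1):1,C:2);")
    states = pd.DataFrame({sp: ["MBG"] * 5 for sp in "ABC"})
    fit = fit_mk_equal_rates(states, tree)
    assert fit.boundary and fit.q < 1e-5


def test_fit_branch_scaling_identity():
    cfg = SimulationConfig(seed=5, n_species=8)
    tree = simulate_tree(cfg)
    rng = np.random.default_rng(2)
    states = simulate_bias_states(tree, 400, q=0.3, rng=rng)
    fit1 = fit_mk_equal_rates(states, tree)
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length *= 2.0
    fit2 = fit_mk_equal_rates(states, tree)
    assert fit2.q == pytest.approx(fit1.q / 2.0, rel=1e-3)


def test_fit_recovers_simulation_rate():
    cfg = SimulationConfig(seed=9, n_species=10)
    tree = simulate_tree(cfg)
    rng = np.random.default_rng(3)
    states = simulate_bias_states(tree, 2000, q=0.1, rng=rng)
    fit = fit_mk_equal_rates(states, tree)
    assert fit.q == pytest.approx(0.1, rel=0.25)


# ---------------------------------------------------------------------------
# turnover counting

def test_count_turnover_rules():
    tree = tree_from_newick("((A:1,B:1)n1:1,C:2)root;")
    tips = pd.DataFrame({"A": ["MBG", "FBG"], "B": ["U", "U"],
                         "C": ["U", "U"]})
    nodes = pd.DataFrame({"n1": ["U", "MBG"], "root": ["U", "MBG"]})
    out = count_turnovers(tips, nodes, tree).set_index("branch")
    # gene 1: U(n1) -> MBG(A): gain; gene 2: MBG(n1) -> FBG(A): loss + gain
    assert out.loc["A", "gains_MBG"] == 1
    assert out.loc["A", "losses_MBG"] == 1
    assert out.loc["A", "gains_FBG"] == 1
    assert out.loc["B", "losses_MBG"] == 1  # gene2 MBG -> U
    counts = out.attrs["node_counts"]
    assert counts["n1"]["MBG"] == 1 and counts["n1"]["U"] == 1


def test_turnover_conservation_identity():
    """Along every root-to-tip path, net gains - losses telescopes to the
    tip-state tally minus the root-state tally, per direction."""
    cfg = SimulationConfig(seed=11, n_species=8)
    tree = simulate_tree(cfg)
    rng = np.random.default_rng(4)
    states = simulate_bias_states(tree, 300, q=0.15, rng=rng)
    fit = fit_mk_equal_rates(states, tree)
    nodes = joint_ancestral_states(states, tree, fit)
    out = count_turnovers(states, nodes, tree).set_index("branch")
    parent_of = out["parent"].to_dict()
    root_label = nodes.columns[-1]
    for tip in states.columns:
        path = []
        cur = tip
        while cur in parent_of:
            path.append(cur)
            cur = parent_of[cur]
        assert cur == root_label
        for direction in ("MBG", "FBG"):
            net = sum(out.loc[b, f"gains_{direction}"]
                      - out.loc[b, f"losses_{direction}"] for b in path)
            tip_total = int((states[tip] == direction).sum())
            root_total = int((nodes[root_label] == direction).sum())
            assert net == tip_total - root_total


def test_turnovers_match_truth_at_low_rate():
    """With rare transitions the reconstruction recovers the true history."""
    cfg = SimulationConfig(seed=13, n_species=10)
    tree = simulate_tree(cfg)
    rng = np.random.default_rng(8)
    # record true node states by simulating on all nodes
    for i, n in enumerate(tree.preorder_node_iter()):
        if not n.is_leaf():
            n.label = f"node{i}"
    states = simulate_bias_states(tree, 500, q=5e-4, rng=rng)
    fit = fit_mk_equal_rates(states, tree)
    nodes = joint_ancestral_states(states, tree, fit)
    out = count_turnovers(states, nodes, tree)
    # expected state changes: ~2q x total tree length x genes (~30 here)
    total = out[["gains_MBG", "losses_MBG", "gains_FBG",
                 "losses_FBG"]].to_numpy().sum()
    assert 0 < total < 80


# ---------------------------------------------------------------------------
# PGLS

def test_pgls_star_tree_equals_ols():
    star = tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")
    rng = np.random.default_rng(1)
    x = pd.Series(rng.normal(size=5), index=list("ABCDE"))
    y = 2 * x + pd.Series(rng.normal(0, 0.1, 5), index=list("ABCDE"))
    fit = ancestral.pgls_trait_association(y, x, star)
    ols = np.polyfit(x.values, y.values, 1)
    assert fit["slope"] == pytest.approx(ols[0], rel=1e-10)
    assert fit["intercept"] == pytest.approx(ols[1], rel=1e-8)


def test_pgls_constant_trait_raises():
    star = tree_from_newick("(A:1,B:1,C:1,D:1);")
    y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
    x = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("ABCD"))
    with pytest.raises(ValueError, match="constant"):
        ancestral.pgls_trait_association(y, x, star)


def test_pgls_recovers_slope_under_brownian_noise():
    cfg = SimulationConfig(seed=21, n_species=12)
    tree = simulate_tree(cfg)
    sp = sorted(t.taxon.label for t in tree.leaf_node_iter())
    C = brownian_covariance(tree, sp)
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(sp)))
    rng = np.random.default_rng(5)
    covered = 0
    n_rep = 30
    from scipy import stats as sstats
    for _ in range(n_rep):
        x = pd.Series(rng.normal(size=len(sp)), index=sp)
        y = 2.0 * x + pd.Series(L @ rng.standard_normal(len(sp)) * 0.5, index=sp)
        fit = ancestral.pgls_trait_association(y, x, tree)
        tcrit = sstats.t.ppf(0.975, df=fit["n"] - 2)
        lo = fit["slope"] - tcrit * fit["se_slope"]
        hi = fit["slope"] + tcrit * fit["se_slope"]
        covered += lo <= 2.0 <= hi
    assert covered / n_rep >= 0.9


def test_pgls_needs_four_species():
    star = tree_from_newick("(A:1,B:1,C:1);")
    s = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
    with pytest.raises(ValueError, match="4"):
        ancestral.pgls_trait_association(s, s, star)
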