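"""Expression phylogenies and expression-divergence statistics.

Species are compared by Spearman's ρ between their mean expression profiles;
the distance 1 − ρ feeds a neighbour-joining tree per organ and gene class
(female-biased, male-biased, unbiased). Root-to-tip path lengths measure
accumulated expression divergence per lineage; Robinson–Foulds distances
compare expression-tree topologies to the time-calibrated species tree; the
decay of ρ with divergence time and the per-branch rate (1 − ρ)/t quantify
expression evolution over time.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "root_to_tip_lengths",
    "rf_distance",
    "divergence_times",
    "divergence_regression",
    "expression_rate",
    "per_lg_correlation",
]


def spearman_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 − Spearman's ρ between profile columns (species).

    ``profiles`` is gene×species; ties get average ranks. Raises on a
    constant profile, whose ranks carry no information.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 genes to rank profiles")
    for col in profiles.columns:
        if profiles[col].nunique() == 1:
            raise ValueError(f"constant expression profile for {col!r}")
    rho = profiles.rank(method="average").corr(method="pearson")
    d = 1.0 - rho
    np.fill_diagonal(d.values, 0.0)
    return d


def _nj_topology(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbour joining with deterministic tie-breaking (lowest index pair)
    and negative branch lengths clamped to zero, the deficit moved to the
    sister branch."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    D = D.astype(float).copy()
    active = list(range(n))
    if n == 2:
        root = tree.seed_node
        for idx in active:
            nodes[idx].edge.length = D[0, 1] / 2.0
            root.add_child(nodes[idx])
        tree.is_rooted = False
        return tree
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair among minima: lexicographic over current order
        flat = np.argwhere(Q == Q.min())
        i_loc, j_loc = min((min(a, b), max(a, b)) for a, b in flat)
        i, j = active[i_loc], active[j_loc]
        li = 0.5 * sub[i_loc, j_loc] + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = sub[i_loc, j_loc] - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new distances
        new_d = 0.5 * (D[active, i] + D[active, j] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_d
        D[active, k] = new_d
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]
    # resolve the final star of three
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lens = [max(x, 0.0) for x in (la, lb, lc)]
    root = tree.seed_node
    for idx, ln in zip((a, b, c), lens):
        nodes[idx].edge.length = ln
        root.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Unrooted neighbour-joining tree from a symmetric distance matrix.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.
    """
    labels = [str(c) for c in distances.columns]
    return _nj_topology(distances.to_numpy(dtype=float), labels)


def _split_set(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each as the smaller-side tip set
    (ties by sorted labels)."""
    tips = {t.taxon.label for t in tree.leaf_node_iter()}
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(tips - side)
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> tuple[int, float]:
    """Robinson–Foulds distance and its normalized variant.

    RF counts nontrivial bipartitions present in exactly one tree; the
    normalized value divides by the total number of nontrivial splits in
    both trees (0 when both trees are stars).
    """
    tips_a = {t.taxon.label for t in tree_a.leaf_node_iter()}
    tips_b = {t.taxon.label for t in tree_b.leaf_node_iter()}
    if tips_a != tips_b:
        raise ValueError(f"tip sets differ: {sorted(tips_a ^ tips_b)}")
    sa, sb = _split_set(tree_a), _split_set(tree_b)
    rf = len(sa ^ sb)
    total = len(sa) + len(sb)
    return rf, (rf / total if total else 0.0)


def bootstrap_supports(profiles: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0) -> dendropy.Tree:
    """NJ tree with split supports from gene-resampling bootstrap.

    Genes (rows) are resampled with replacement ``n_boot`` times; the support
    of a split is the fraction of replicate trees containing it, stored as
    each internal node's label.
    """
    tree = nj_tree(spearman_distance_matrix(profiles))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    n_genes = profiles.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = profiles.iloc[idx]
        try:
            bt = nj_tree(spearman_distance_matrix(boot))
        except ValueError:  # degenerate resample (constant profile)
            continue
        for s in _split_set(bt):
            counts[s] = counts.get(s, 0) + 1
    tips = {t.taxon.label for t in tree.leaf_node_iter()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, frozenset(tips - side),
                  key=lambda s: (len(s), tuple(sorted(s))))
        node.label = f"{counts.get(key, 0) / n_boot:.3f}"
    return tree


def root_tree(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Root a tree at an outgroup tip edge, or at the midpoint when no
    outgroup is given or present."""
    t = tree.clone(depth=1)
    og = None
    if outgroup is not None:
        og = next((l for l in t.leaf_node_iter()
                   if l.taxon.label == outgroup), None)
    if og is not None:
        t.to_outgroup_position(og, update_bipartitions=False)
    else:
        t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def root_to_tip_lengths(tree: dendropy.Tree) -> pd.Series:
    """Cumulative branch length from the root to every tip of a rooted tree."""
    if not tree.is_rooted:
        raise ValueError("tree must be rooted (use root_tree first)")
    out = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        node = leaf
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = total
    return pd.Series(out, name="root_to_tip").sort_index()


def divergence_times(species_tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise divergence times: patristic path length between tips (twice
    the MRCA age on an ultrametric time tree)."""
    pdm = species_tree.phylogenetic_distance_matrix()
    taxa = sorted(species_tree.taxon_namespace, key=lambda t: t.label)
    rows = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            rows.append((a.label, b.label, pdm.patristic_distance(a, b)))
    return pd.DataFrame(rows, columns=["species_a", "species_b", "t"])


def divergence_regression(profiles: pd.DataFrame,
                          species_tree: dendropy.Tree) -> dict:
    """Decay of expression correlation with divergence time.

    For every species pair present in both the profile columns and the tree:
    Spearman ρ of the two profiles against patristic divergence time; returns
    the pair table, the least-squares slope/intercept of ρ on t, and the
    Pearson correlation with its p-value (p is nan with <3 pairs).
    """
    times = divergence_times(species_tree)
    cols = set(map(str, profiles.columns))
    rows = []
    for rec in times.itertuples(index=False):
        if rec.species_a in cols and rec.species_b in cols:
            rho = stats.spearmanr(profiles[rec.species_a],
                                  profiles[rec.species_b]).statistic
            rows.append((rec.species_a, rec.species_b, rec.t, float(rho)))
    pairs = pd.DataFrame(rows, columns=["species_a", "species_b", "t", "rho"])
    out = {"pairs": pairs, "slope": math.nan, "intercept": math.nan,
           "r": math.nan, "p": math.nan}
    if len(pairs) >= 2 and pairs["t"].nunique() > 1:
        res = stats.linregress(pairs["t"], pairs["rho"])
        out.update(slope=res.slope, intercept=res.intercept, r=res.rvalue,
                   p=res.pvalue if len(pairs) >= 3 else math.nan)
    return out


def expression_rate(rho: float, t: float) -> float:
    """Rate of expression change (1 − ρ) / t per unit divergence time."""
    if t <= 0:
        return math.nan
    return (1.0 - rho) / t


def per_lg_correlation(profiles: pd.DataFrame, gene_lg: pd.Series,
                       min_genes: int = 3) -> tuple[pd.DataFrame, dict]:
    """Between-taxa expression correlations per linkage group.

    For each LG with ≥ ``min_genes`` genes: Spearman ρ for every pair of
    profile columns over that LG's genes. Returns the long table of per-LG ρ
    values and a Kruskal–Wallis test across LGs (nan p with <2 usable LGs).
    """
    lg_of = gene_lg.reindex(profiles.index)
    rows = []
    for lg, genes in lg_of.groupby(lg_of):
        sub = profiles.loc[genes.index]
        if len(sub) < min_genes:
            continue
        cols = list(sub.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rho = stats.spearmanr(sub[a], sub[b]).statistic
                rows.append((lg, str(a), str(b), float(rho)))
    table = pd.DataFrame(rows, columns=["lg", "species_a", "species_b", "rho"])
    groups = [g["rho"].to_numpy() for _, g in table.groupby("lg")]
    if len(groups) >= 2:
        H, p = stats.kruskal(*groups)
        test = {"H": float(H), "p": float(p), "n_lgs": len(groups)}
    else:
        test = {"H": math.nan, "p": math.nan, "n_lgs": len(groups)}
    return table, test
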