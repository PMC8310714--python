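"""Ancestral reconstruction of sex-bias states and turnover counting.

Sex-bias status (unbiased U, female-biased FBG, male-biased MBG) is modelled
as a 3-state continuous-time Markov chain with one symmetric rate q (the Mk
equal-rates model): P_ii(t) = 1/3 + (2/3)e^{-3qt}, P_ij(t) = 1/3 −
(1/3)e^{-3qt}. The rate is fitted by maximum likelihood with Felsenstein's
pruning algorithm summed over genes; per gene the jointly most probable
internal-state assignment is found by max-product dynamic programming, ties
broken toward U then FBG then MBG. Gains and losses of biased status are
counted per branch from the parent→child state changes. Trait associations
of terminal-branch turnover totals use phylogenetic GLS with a Brownian
covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "STATES",
    "MkModelFit",
    "transition_matrix",
    "fit_mk_equal_rates",
    "joint_ancestral_states",
    "count_turnovers",
    "brownian_covariance",
    "pgls_trait_association",
]

STATES = ("U", "FBG", "MBG")  # index order is also the tie-break preference
_STATE_IDX = {s: i for i, s in enumerate(STATES)}
MISSING = -1


def transition_matrix(q: float, t: float) -> np.ndarray:
    """3-state equal-rates transition probabilities over branch length t."""
    e = math.exp(-3.0 * q * t)
    same = 1.0 / 3.0 + 2.0 / 3.0 * e
    diff = 1.0 / 3.0 - 1.0 / 3.0 * e
    P = np.full((3, 3), diff)
    np.fill_diagonal(P, same)
    return P


@dataclass
class MkModelFit:
    q: float
    log_likelihood: float
    converged: bool
    boundary: bool = False


class _TreeIndex:
    """Postorder arrays for vectorized pruning over many genes."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.nodes
        ]
        self.edge_len = np.array(
            [n.edge.length if n.edge.length else 0.0 for n in self.nodes]
        )
        self.is_leaf = [n.is_leaf() for n in self.nodes]
        self.labels = [
            n.taxon.label if n.is_leaf() else (n.label or f"node{i}")
            for i, n in enumerate(self.nodes)
        ]
        self.root = len(self.nodes) - 1


def _state_codes(states: pd.DataFrame) -> np.ndarray:
    """gene×species states to integer codes (missing/NaN → MISSING)."""
    def code(v):
        if pd.isna(v) or v == "":
            return MISSING
        return _STATE_IDX[v]
    return states.map(code).to_numpy(dtype=int)


def _pruning_loglik(q: float, ti: _TreeIndex, tip_codes: dict[str, np.ndarray],
                    n_genes: int) -> float:
    """Summed pruning log-likelihood across genes at rate q (uniform root)."""
    partials = [None] * len(ti.nodes)
    scale = np.zeros(n_genes)
    for i, node in enumerate(ti.nodes):
        if ti.is_leaf[i]:
            codes = tip_codes[ti.labels[i]]
            L = np.ones((n_genes, 3))
            obs = codes != MISSING
            L[obs] = np.eye(3)[codes[obs]]
            partials[i] = L
        else:
            L = np.ones((n_genes, 3))
            for c in ti.children[i]:
                P = transition_matrix(q, ti.edge_len[c])
                L *= partials[c] @ P.T
                partials[c] = None
            m = L.max(axis=1)
            m[m == 0] = 1.0
            scale += np.log(m)
            partials[i] = L / m[:, None]
    root_like = partials[ti.root].mean(axis=1)  # uniform 1/3 prior
    root_like = np.maximum(root_like, 1e-300)
    return float(np.sum(np.log(root_like) + scale))


def fit_mk_equal_rates(states: pd.DataFrame, tree: dendropy.Tree,
                       q_max: float = 100.0) -> MkModelFit:
    """ML estimate of the single Mk transition rate from gene×species states.

    ``states`` has genes as rows and species (tree tip labels) as columns
    with values in {U, FBG, MBG} or NaN for missing; missing tips are
    integrated out with a uniform partial likelihood. All-monomorphic data
    drive q to the zero boundary, reported with ``boundary=True``.
    """
    ti = _TreeIndex(tree)
    tips = [lbl for i, lbl in enumerate(ti.labels) if ti.is_leaf[i]]
    missing_cols = set(tips) - set(states.columns)
    if missing_cols:
        raise ValueError(f"states table lacks tree tips: {sorted(missing_cols)}")
    codes = _state_codes(states[list(states.columns)])
    tip_codes = {t: _state_codes(states[[t]]).ravel() for t in tips}
    n_genes = states.shape[0]
    if n_genes == 0:
        raise ValueError("need at least one gene")

    def nll(q):
        return -_pruning_loglik(q, ti, tip_codes, n_genes)

    # the likelihood is flat for large q: bracket on a log grid first
    grid = np.concatenate([[1e-9], np.geomspace(1e-6, q_max, 40)])
    vals = np.array([nll(q) for q in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    q_hat = float(res.x)
    ll = -float(res.fun)
    if vals[k] < res.fun:  # keep the better of grid and refinement
        q_hat, ll = float(grid[k]), -float(vals[k])
    boundary = q_hat <= 1e-6
    return MkModelFit(q=q_hat, log_likelihood=ll,
                      converged=bool(res.success), boundary=boundary)


def joint_ancestral_states(states: pd.DataFrame, tree: dendropy.Tree,
                           fit: MkModelFit) -> pd.DataFrame:
    """Jointly most probable internal-node states per gene.

    Max-product dynamic programming over the tree at the fitted rate, with
    ties broken toward U, then FBG, then MBG (the STATES order). Returns a
    gene×node frame whose columns are internal-node labels (assigned
    ``node<i>`` in postorder where unlabelled).
    """
    ti = _TreeIndex(tree)
    q = max(fit.q, 1e-9)
    n_genes = states.shape[0]
    tip_codes = {ti.labels[i]: _state_codes(states[[ti.labels[i]]]).ravel()
                 for i in range(len(ti.nodes)) if ti.is_leaf[i]}
    logP = {}
    for i in range(len(ti.nodes)):
        with np.errstate(divide="ignore"):
            logP[i] = np.log(transition_matrix(q, ti.edge_len[i]))
    # C[i][g, j] = best log-prob of subtree at i given parent state j;
    # B[i][g, j] = argmax state of node i under parent state j
    C = [None] * len(ti.nodes)
    B = [None] * len(ti.nodes)
    for i, node in enumerate(ti.nodes):
        if ti.is_leaf[i]:
            codes = tip_codes[ti.labels[i]]
            c = np.zeros((n_genes, 3))
            obs = codes != MISSING
            c[obs] = logP[i][:, codes[obs]].T
            C[i] = c
        else:
            inner = np.zeros((n_genes, 3))  # log-prob of children given own state k
            for ch in ti.children[i]:
                inner += C[ch]
            if i == ti.root:
                tot = inner + math.log(1.0 / 3.0)
                B[i] = tot.argmax(axis=1)  # ties → lowest index (U first)
                C[i] = tot.max(axis=1)
            else:
                # over own state k for each parent state j
                scored = logP[i][None, :, :] + inner[:, None, :]  # g × j × k
                B[i] = scored.argmax(axis=2)
                C[i] = scored.max(axis=2)
    # top-down assignment
    assign = np.full((n_genes, len(ti.nodes)), -1, dtype=int)
    assign[:, ti.root] = B[ti.root]
    for i in range(len(ti.nodes) - 2, -1, -1):
        parent = next(j for j in range(len(ti.nodes))
                      if i in ti.children[j])
        if ti.is_leaf[i]:
            continue
        ps = assign[:, parent]
        assign[:, i] = B[i][np.arange(n_genes), ps]
    internal = [i for i in range(len(ti.nodes)) if not ti.is_leaf[i]]
    out = pd.DataFrame(
        {ti.labels[i]: [STATES[s] for s in assign[:, i]] for i in internal},
        index=states.index,
    )
    return out


def count_turnovers(states: pd.DataFrame, node_states: pd.DataFrame,
                    tree: dendropy.Tree) -> pd.DataFrame:
    """Per-branch gains and losses of MBG and FBG status.

    A branch from parent state a to child state b contributes: U→MBG a
    gain_MBG; MBG→U a loss_MBG; MBG→FBG one loss_MBG plus one gain_FBG (and
    symmetrically for FBG). Branches to tips with missing states are skipped.
    Returns one row per branch keyed by the child node label, plus per-node
    counts of reconstructed MBGs/FBGs in ``attrs['node_counts']``.
    """
    ti = _TreeIndex(tree)
    child_states = {}
    for i in range(len(ti.nodes)):
        lbl = ti.labels[i]
        if ti.is_leaf[i]:
            child_states[i] = states[lbl].to_numpy(dtype=object)
        else:
            child_states[i] = node_states[lbl].to_numpy(dtype=object)
    rows = []
    for parent in range(len(ti.nodes)):
        for c in ti.children[parent]:
            pa, ch = child_states[parent], child_states[c]
            ok = pd.notna(pa) & pd.notna(ch)
            pa, ch = pa[ok], ch[ok]
            gains_m = int(np.sum((pa != "MBG") & (ch == "MBG")))
            losses_m = int(np.sum((pa == "MBG") & (ch != "MBG")))
            gains_f = int(np.sum((pa != "FBG") & (ch == "FBG")))
            losses_f = int(np.sum((pa == "FBG") & (ch != "FBG")))
            rows.append((ti.labels[c], ti.labels[parent], ti.is_leaf[c],
                         gains_m, losses_m, gains_f, losses_f))
    out = pd.DataFrame(rows, columns=["branch", "parent", "terminal",
                                      "gains_MBG", "losses_MBG",
                                      "gains_FBG", "losses_FBG"])
    node_counts = {
        lbl: {s: int((node_states[lbl] == s).sum()) for s in STATES}
        for lbl in node_states.columns
    }
    out.attrs["node_counts"] = node_counts
    return out


def brownian_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-MRCA path length."""
    t = tree.clone(depth=1)
    t.is_rooted = True
    t.calc_node_root_distances(return_leaf_distances_only=False)
    pdm = {}
    leaves = {l.taxon.label: l for l in t.leaf_node_iter()}
    missing = set(taxa) - set(leaves)
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i > j:
                C[i, j] = C[j, i]
                continue
            if a == b:
                C[i, j] = leaves[a].root_distance
            else:
                mrca = t.mrca(taxa=[leaves[a].taxon, leaves[b].taxon])
                C[i, j] = mrca.root_distance
    return C


def pgls_trait_association(response: pd.Series, trait: pd.Series,
                           tree: dendropy.Tree) -> dict:
    """Phylogenetic GLS regression of a per-species response on one trait.

    Residual covariance is Brownian (σ²·C with C from shared branch lengths);
    σ² is profiled out. Reports slope, intercept, their standard errors and
    t-test p-values (df = n − 2). Needs ≥4 species with complete data; a
    constant trait raises a collinearity error.
    """
    common = [s for s in response.index if s in trait.index
              and pd.notna(response[s]) and pd.notna(trait[s])]
    if len(common) < 4:
        raise ValueError(f"need >= 4 species with complete data, got {len(common)}")
    y = response[common].to_numpy(dtype=float)
    x = trait[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: slope not identifiable")
    C = brownian_covariance(tree, common)
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    X = np.column_stack([np.ones_like(x), x])
    XtCi = X.T @ Ci
    beta_cov = np.linalg.inv(XtCi @ X)
    beta = beta_cov @ XtCi @ y
    resid = y - X @ beta
    n, p = len(y), 2
    sigma2 = float(resid @ Ci @ resid) / (n - p)
    se = np.sqrt(np.diag(beta_cov) * sigma2)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    return {
        "n": n,
        "intercept": float(beta[0]), "slope": float(beta[1]),
        "se_intercept": float(se[0]), "se_slope": float(se[1]),
        "t_slope": float(tstat[1]), "p_slope": float(pvals[1]),
        "p_intercept": float(pvals[0]),
        "sigma2": sigma2,
    }
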