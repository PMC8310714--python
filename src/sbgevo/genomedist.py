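"""Genomic-distribution statistics for sex-biased genes.

Per linkage group and species, a one-sided Fisher's exact test asks whether
the LG's MBG:FBG balance departs from the rest of the genome in the
direction of the observed difference (an FBG excess is "feminization", an
MBG excess "masculinization" — on a differentiated XY, demasculinization of
the X appears as the same tail). Sex-chromosome versus autosome contrasts of
per-gene statistics use Mann–Whitney tests; across-category comparisons use
Kruskal–Wallis with Wilcoxon post hocs, BH-adjusted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust  # re-exported: one adjustment routine package-wide

__all__ = [
    "fisher_one_sided",
    "mann_whitney_u",
    "kruskal_wallis",
    "bh_adjust",
    "lg_enrichment",
    "sexchr_vs_autosome_compare",
]


def fisher_one_sided(table, direction: str) -> float:
    """One-sided Fisher's exact p for a 2×2 count table.

    ``table`` rows are (on-LG, off-LG) and columns (MBG, FBG);
    ``direction='feminization'`` tests for an FBG excess on the LG (equally a
    MBG deficit), ``'masculinization'`` the opposite tail. A zero margin
    yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    alternative = {"feminization": "less", "masculinization": "greater"}[direction]
    return float(stats.fisher_exact(t, alternative=alternative)[1])


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Mann–Whitney U with average-rank ties.

    Exact p when min(n, m) ≤ ``exact_max_n`` and the data are tie-free,
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = ("exact" if min(x.size, y.size) <= exact_max_n and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; chi-squared p with k−1 df.

    All-identical values give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def lg_enrichment(bias_table: pd.DataFrame, annotation: pd.DataFrame,
                  organ: str = "gonad") -> pd.DataFrame:
    """Per-species, per-LG one-sided Fisher screen for feminization or
    masculinization of the LG's SBG complement.

    For each species: the 2×2 table of MBG/FBG counts on the LG versus the
    rest of the genome; the tail tested follows the sign of the on-LG
    MBG−FBG count difference relative to the genome-wide ratio — reported
    with its direction. A zero difference reports p = 1, direction "none".
    """
    lg_of = annotation.set_index("gene")["lg"]
    sub = bias_table[(bias_table["organ"] == organ)
                     & bias_table["direction"].isin(["MBG", "FBG"])].copy()
    sub["lg"] = sub["gene"].map(lg_of)
    rows = []
    for sp, grp in sub.groupby("species"):
        tot_m = int((grp["direction"] == "MBG").sum())
        tot_f = int((grp["direction"] == "FBG").sum())
        for lg in sorted(annotation["lg"].unique()):
            on = grp[grp["lg"] == lg]
            m_on = int((on["direction"] == "MBG").sum())
            f_on = int((on["direction"] == "FBG").sum())
            diff = m_on - f_on
            table = [[m_on, f_on], [tot_m - m_on, tot_f - f_on]]
            if diff < 0:
                direction = "feminization"
            elif diff > 0:
                direction = "masculinization"
            else:
                rows.append((sp, lg, m_on, f_on, "none", 1.0))
                continue
            p = fisher_one_sided(table, direction)
            rows.append((sp, lg, m_on, f_on, direction, p))
    out = pd.DataFrame(rows, columns=["species", "lg", "n_mbg", "n_fbg",
                                      "direction", "p"])
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def sexchr_vs_autosome_compare(gene_stats: pd.DataFrame,
                               sexchr_lgs: set[str] | list[str],
                               statistics: list[str],
                               class_col: str = "bias_class") -> pd.DataFrame:
    """Mann–Whitney contrasts of sex-chromosome genes vs pooled autosomes.

    ``gene_stats`` has one row per gene with an ``lg`` column, a gene-class
    column (FBG/MBG/unbiased) and the statistic columns to compare. Classes
    with no sex-chromosome genes are skipped. p-values are BH-adjusted over
    the emitted comparisons.
    """
    sexchr_lgs = set(sexchr_lgs)
    rows = []
    on_sex = gene_stats["lg"].isin(sexchr_lgs)
    for cls, grp in gene_stats.groupby(class_col):
        sx = grp[on_sex.reindex(grp.index)]
        au = grp[~on_sex.reindex(grp.index)]
        for stat in statistics:
            x = sx[stat].dropna().to_numpy()
            y = au[stat].dropna().to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):
                u, p = float(x.size * y.size / 2), 1.0
            else:
                u, p = mann_whitney_u(x, y)
            rows.append((cls, stat, x.size, y.size,
                         float(np.median(x)), float(np.median(y)), u, p))
    out = pd.DataFrame(rows, columns=["bias_class", "statistic", "n_sexchr",
                                      "n_autosome", "median_sexchr",
                                      "median_autosome", "U", "p"])
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
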