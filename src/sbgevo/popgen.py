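"""Per-site and per-gene intersex population-genetic statistics.

Intersex Fst treats males and females of one species as two "populations";
X–Y sequence divergence inflates male–female allele-frequency differences in
the non-recombining region, so elevated intersex Fst marks sex-linked genes.
Per-gene Fst aggregates Hudson's per-site moment components as a ratio of
sums, Σα / Σ(α+β), which shrinks noisy per-site ratios toward the regional
value. Nucleotide diversity is corrected by the number of covered (variant
plus invariant) sites per gene, and Tajima's D uses the standard 1989
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SiteAlleleCounts",
    "apply_site_filters",
    "hudson_alpha_beta",
    "gene_fst_ratio_of_sums",
    "site_pi",
    "gene_pi_corrected",
    "tajimas_d",
    "build_sfs",
    "gene_stats_table",
]


@dataclass
class SiteAlleleCounts:
    """Filtered allele counts at one site, overall and split by sex.

    ``n_*`` are sampled allele copies (2 × covered diploids, minus missing
    genotypes), ``d_*`` derived/alternate allele copies among them.
    """

    lg: str
    pos: int  # 1-based
    n_all: int
    d_all: int
    n_male: int = 0
    d_male: int = 0
    n_female: int = 0
    d_female: int = 0
    covered_individuals: int = 0
    total_depth: int = 0
    fst_eligible: bool = False

    def __post_init__(self) -> None:
        for d, n in ((self.d_all, self.n_all), (self.d_male, self.n_male),
                     (self.d_female, self.n_female)):
            if not 0 <= d <= n:
                raise ValueError(f"allele count {d} outside [0, {n}] at "
                                 f"{self.lg}:{self.pos}")


def apply_site_filters(
    sites: pd.DataFrame,
    *,
    min_individuals: int = 3,
    min_total_depth: int = 3,
    min_per_sex: int = 2,
    min_base_quality: float = 13.0,
) -> pd.DataFrame:
    """Apply the site-level coverage/quality filters.

    ``sites`` needs columns ``lg, pos, n_covered, total_depth`` plus
    ``n_covered_male, n_covered_female`` and optionally ``qual``. Returns the
    general-pass subset with a boolean ``fst_eligible`` column: the general
    stream keeps sites present in at least ``min_individuals`` individuals
    with total depth at least ``min_total_depth`` (and base quality at least
    ``min_base_quality`` when a ``qual`` column is present); Fst additionally
    requires at least ``min_per_sex`` covered individuals of each sex.
    """
    required = {"lg", "pos", "n_covered", "total_depth"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    keep = (sites["n_covered"] >= min_individuals) & (
        sites["total_depth"] >= min_total_depth
    )
    if "qual" in sites.columns:
        keep &= sites["qual"].fillna(np.inf) >= min_base_quality
    out = sites.loc[keep].copy()
    if {"n_covered_male", "n_covered_female"} <= set(out.columns):
        out["fst_eligible"] = (out["n_covered_male"] >= min_per_sex) & (
            out["n_covered_female"] >= min_per_sex
        )
    else:
        out["fst_eligible"] = False
    return out


def hudson_alpha_beta(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Hudson's per-site moment components of Fst between two samples.

    ``alpha`` estimates the between-population variance component and can be
    negative (method-of-moments); ``beta`` the remaining within component, so
    the per-site estimate of Fst is ``alpha / (alpha + beta)``.

    Parameters are sample allele frequencies ``p`` and sampled allele copy
    numbers ``n`` (≥ 2 each) for the two groups.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need at least 2 allele copies per group, got {n1}, {n2}")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    alpha = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1 - 1)
        - p2 * (1.0 - p2) / (n2 - 1)
    )
    beta = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return alpha, beta


def gene_fst_ratio_of_sums(alphas, betas) -> float:
    """Per-gene Fst as the ratio of sums Σα / Σ(α+β) over eligible sites.

    Negative-α sites are retained in the sums. Returns ``nan`` when there are
    no sites or the denominator is zero.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if alphas.size == 0:
        return math.nan
    denom = float(np.sum(alphas + betas))
    if denom == 0.0:
        return math.nan
    return float(np.sum(alphas)) / denom


def site_pi(d: int, n: int) -> float:
    """Per-site nucleotide diversity 2·d·(n−d) / (n·(n−1)).

    Equals the fraction of distinct haplotype pairs that differ at the site.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 allele copies, got {n}")
    if not 0 <= d <= n:
        raise ValueError(f"derived count {d} outside [0, {n}]")
    return 2.0 * d * (n - d) / (n * (n - 1))


def gene_pi_corrected(site_pis, n_covered_sites: int) -> float:
    """Gene-level π: summed variant-site π divided by all covered sites.

    Invariant covered sites contribute 0 to the numerator and 1 to the
    denominator, so genes with patchy coverage are comparable.
    """
    site_pis = np.asarray(site_pis, dtype=float)
    if n_covered_sites < 1:
        return math.nan
    if site_pis.size > n_covered_sites:
        raise ValueError("more variant sites than covered sites")
    return float(np.sum(site_pis)) / n_covered_sites


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(S: int, site_pis, n: int) -> float:
    """Tajima's D from segregating sites and summed per-site π at sample size n.

    ``site_pis`` are the per-site diversities of the S variant sites (their sum
    is the mean pairwise difference π for the region). Undefined (nan) when
    S = 0 or the variance term is non-positive. ``n`` is the number of sampled
    allele copies, assumed constant across sites.
    """
    if n < 4:
        raise ValueError(f"Tajima's D needs n >= 4 sampled copies, got {n}")
    if S == 0:
        return math.nan
    pi_total = float(np.sum(np.asarray(site_pis, dtype=float)))
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def build_sfs(derived_counts, n: int, folded: bool = False) -> np.ndarray:
    """Site frequency spectrum from per-site derived allele counts.

    Unfolded: classes 0..n of derived-allele count. Folded (no ancestral
    state): classes 0..⌊n/2⌋ of minor-allele count, d ↦ min(d, n−d).
    """
    d = np.asarray(derived_counts, dtype=int)
    if np.any((d < 0) | (d > n)):
        raise ValueError("derived counts outside [0, n]")
    if folded:
        d = np.minimum(d, n - d)
        return np.bincount(d, minlength=n // 2 + 1)
    return np.bincount(d, minlength=n + 1)


def gene_stats_table(
    sites: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    min_n_for_d: int = 4,
) -> pd.DataFrame:
    """Aggregate filtered per-site counts into per-gene statistics.

    ``sites`` is an ``apply_site_filters`` output augmented with allele counts
    (``n_all, d_all, n_male, d_male, n_female, d_female``); ``annotation`` has
    ``gene, lg, start, end`` with 1-based inclusive intervals. A site is
    assigned to the first gene (in annotation order) whose interval contains
    it. Returns one row per annotated gene: ``fst`` (ratio of sums over
    Fst-eligible sites), ``pi`` (coverage-corrected), ``S``, ``tajimas_d``
    (at the gene-wise minimum sample size, nan when S = 0 or n < 4),
    ``n_sites`` (variant), ``n_covered`` (all pass-filter sites in the gene).
    """
    rows = []
    sites_by_lg = {lg: df.sort_values("pos") for lg, df in sites.groupby("lg")}
    for rec in annotation.itertuples(index=False):
        lgdf = sites_by_lg.get(rec.lg)
        if lgdf is None:
            rows.append((rec.gene, rec.lg, math.nan, math.nan, 0, math.nan, 0, 0))
            continue
        inside = lgdf[(lgdf["pos"] >= rec.start) & (lgdf["pos"] <= rec.end)]
        n_covered = len(inside)
        variant = inside[(inside["d_all"] > 0) & (inside["d_all"] < inside["n_all"])]
        S = len(variant)
        pis = [site_pi(int(r.d_all), int(r.n_all)) for r in variant.itertuples()]
        pi = gene_pi_corrected(pis, n_covered) if n_covered else math.nan
        if S > 0:
            n_min = int(variant["n_all"].min())
            d_val = tajimas_d(S, pis, n_min) if n_min >= min_n_for_d else math.nan
        else:
            d_val = math.nan
        el = inside[inside["fst_eligible"]]
        alphas, betas = [], []
        for r in el.itertuples():
            if r.n_male >= 2 and r.n_female >= 2:
                a, b = hudson_alpha_beta(
                    r.d_male / r.n_male, int(r.n_male),
                    r.d_female / r.n_female, int(r.n_female),
                )
                alphas.append(a)
                betas.append(b)
        fst = gene_fst_ratio_of_sums(alphas, betas)
        rows.append((rec.gene, rec.lg, fst, pi, S, d_val, S, n_covered))
    return pd.DataFrame(
        rows,
        columns=["gene", "lg", "fst", "pi", "S", "tajimas_d", "n_sites", "n_covered"],
    )
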