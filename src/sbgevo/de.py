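"""Normalization, QC and sex-biased gene calling from RNA-seq counts.

Counts are TMM-normalized (trimmed mean of M-values between each sample and a
reference sample). Sex bias is tested per species and organ with a
negative-binomial Wald test on the log2 male/female fold change, BH-adjusted
within each species×organ family. A sex-biased gene (SBG) has adjusted
p < 0.05 and |LFC| > 2; the bias strength is binned into the categories
low (2, 2.6), mid [2.6, 4.1), high [4.1, 6.5) and extreme [6.5, ∞) on |LFC|.
LFC > 0 means male-biased (MBG), LFC < 0 female-biased (FBG).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_low_count_genes",
    "tmm_factors",
    "tmm_normalize",
    "vst",
    "qc_flag_samples",
    "test_sex_bias",
    "assign_bias_category",
    "call_all_sex_bias",
    "shared_sbg_sets",
    "expression_variance_check",
]

ALPHA_DEFAULT = 0.05
LFC_THRESHOLD_DEFAULT = 2.0


def filter_low_count_genes(counts: pd.DataFrame, min_total: float = 1.0) -> pd.DataFrame:
    """Drop genes whose summed count across all samples is below ``min_total``.

    A total of exactly ``min_total`` is retained (the filter is "less than").
    """
    if counts.empty:
        warnings.warn("empty count matrix passed to filter_low_count_genes")
        return counts
    keep = counts.sum(axis=1) >= min_total
    return counts.loc[keep]


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    if not np.any(pos):
        return 0.0
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic (binomial) variance of M per gene
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = M.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rM = stats.rankdata(M, method="ordinal")
    rA = stats.rankdata(A, method="ordinal")
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not np.any(keep):
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * M[keep]) / np.sum(w))


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample defaults to the one whose 75th count-fraction
    percentile is closest to the mean across samples. Raises on a sample with
    zero total count.
    """
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    if ref_sample is None:
        uq = (counts / lib).quantile(0.75, axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    logf = {
        s: _tmm_pair_factor(counts[s].to_numpy(), ref, lib[s], lib[ref_sample])
        for s in counts.columns
    }
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()}, name="tmm_factor")
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def tmm_normalize(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.DataFrame:
    """TMM-normalized counts: count / (library size × factor), rescaled to the
    geometric-mean library size so values stay on a count-like scale."""
    factors = tmm_factors(counts, ref_sample)
    lib = counts.sum(axis=0).astype(float)
    scale = float(np.exp(np.log(lib).mean()))
    return counts / (lib * factors) * scale


def vst(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-damping transform used for QC: log2(normalized count + 1)."""
    return np.log2(norm_counts + 1.0)


def qc_flag_samples(counts: pd.DataFrame, metadata: pd.DataFrame,
                    k: int = 3) -> pd.DataFrame:
    """Advisory per-sample QC flags; exclusion is left to the user.

    Flags: ``low_signal`` (median normalized count ~0), ``sex_mismatch``
    (within species×organ, the majority of the k nearest neighbours on VST
    Euclidean distance carries the opposite sex label) and ``organ_mismatch``
    (nearest organ centroid in global VST space is another organ).
    """
    md = metadata.set_index("sample")
    lib = counts.sum(axis=0)
    nonzero = counts.loc[:, lib > 0]
    norm = tmm_normalize(nonzero) if nonzero.shape[1] else nonzero
    flags: list[tuple[str, str]] = []
    for s in counts.columns:
        if lib[s] == 0 or float(norm[s].median() if s in norm else 0.0) <= 0.0:
            flags.append((s, "low_signal"))
    v = vst(norm)
    # sex mislabel: within species & organ
    for (_, _), grp in md.groupby(["species", "organ"]):
        names = [s for s in grp.index if s in v.columns]
        if len(names) <= k:
            continue
        sub = v[names].to_numpy().T
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        sexes = md.loc[names, "sex"].to_numpy()
        for i, s in enumerate(names):
            nn = np.argsort(d2[i])[:k]
            if (sexes[nn] != sexes[i]).sum() > k / 2:
                flags.append((s, "sex_mismatch"))
    # organ grouping in global space
    organs = md.loc[[s for s in v.columns], "organ"]
    cents = {o: v[idx.index].mean(axis=1) for o, idx in organs.groupby(organs)}
    if len(cents) > 1:
        for s in v.columns:
            dists = {o: float(((v[s] - c) ** 2).sum()) for o, c in cents.items()}
            if min(dists, key=dists.get) != md.loc[s, "organ"]:
                flags.append((s, "organ_mismatch"))
    return pd.DataFrame(sorted(set(flags)), columns=["sample", "flag"])


def assign_bias_category(lfc: float) -> str:
    """Bias-strength category from |LFC|: none / low / mid / high / extreme.

    Bins: |LFC| ≤ 2 → none; (2, 2.6) → low; [2.6, 4.1) → mid;
    [4.1, 6.5) → high; ≥ 6.5 → extreme.
    """
    a = abs(lfc)
    if a <= 2.0:
        return "none"
    if a < 2.6:
        return "low"
    if a < 4.1:
        return "mid"
    if a < 6.5:
        return "high"
    return "extreme"


def _trended_dispersion(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Monotone-ish mean–dispersion trend by binned medians, interpolated."""
    ok = mean > 0
    if ok.sum() < 10:
        return np.full_like(disp, float(np.median(disp[ok])) if ok.any() else 0.1)
    lm = np.log(mean[ok])
    order = np.argsort(lm)
    n_bins = max(5, min(20, ok.sum() // 50))
    bins = np.array_split(order, n_bins)
    bx = np.array([lm[b].mean() for b in bins])
    by = np.array([np.median(disp[ok][b]) for b in bins])
    out = np.full(mean.shape, float(np.median(by)))
    out[ok] = np.interp(lm, bx, by)
    return np.maximum(out, 1e-8)


def test_sex_bias(
    norm_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    species: str,
    organ: str,
    *,
    pseudocount: float = 0.5,
    alpha: float = ALPHA_DEFAULT,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Negative-binomial Wald test of male vs female expression for one
    species×organ contrast.

    Per gene: LFC = log2((mean_M + c)/(mean_F + c)) on TMM-normalized counts;
    the Wald statistic uses a delta-method standard error with a per-gene
    method-of-moments dispersion shrunk toward a binned mean–dispersion
    trend. p-values are BH-adjusted within the contrast. Genes with zero
    counts in every sample of both sexes get no p-value (excluded rows).
    Raises ``ValueError`` if either sex has fewer than ``min_reps`` replicates.
    """
    md = metadata.set_index("sample")
    sel = md[(md["species"] == species) & (md["organ"] == organ)]
    males = [s for s in sel[sel["sex"] == "M"].index if s in norm_counts.columns]
    females = [s for s in sel[sel["sex"] == "F"].index if s in norm_counts.columns]
    if len(males) < min_reps or len(females) < min_reps:
        raise ValueError(
            f"{species}/{organ}: need >= {min_reps} replicates per sex "
            f"(got {len(males)} M, {len(females)} F)")
    X_m = norm_counts[males].to_numpy(dtype=float)
    X_f = norm_counts[females].to_numpy(dtype=float)
    n_m, n_f = X_m.shape[1], X_f.shape[1]
    mu_m, mu_f = X_m.mean(1), X_f.mean(1)
    expressed = (mu_m > 0) | (mu_f > 0)
    var_m = X_m.var(1, ddof=1)
    var_f = X_f.var(1, ddof=1)
    # MoM NB dispersion pooled over sexes: var = mu + phi mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (var_m - mu_m) + (var_f - mu_f)
        phi_raw = phi_raw / np.maximum(mu_m**2 + mu_f**2, 1e-300)
    phi_raw = np.clip(np.nan_to_num(phi_raw, nan=0.0), 1e-8, 100.0)
    pooled_mean = (mu_m + mu_f) / 2
    trend = _trended_dispersion(pooled_mean[expressed], phi_raw[expressed])
    phi = np.full(phi_raw.shape, 1e-8)
    df_res = n_m + n_f - 2
    prior_w = 4.0
    phi[expressed] = (df_res * phi_raw[expressed] + prior_w * trend) / (df_res + prior_w)
    c = pseudocount
    lfc = np.log2((mu_m + c) / (mu_f + c))
    ln2sq = math.log(2.0) ** 2
    se2 = ((1.0 / (mu_m + c) + phi) / n_m + (1.0 / (mu_f + c) + phi) / n_f) / ln2sq
    z = lfc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    genes = norm_counts.index.to_numpy()
    out = pd.DataFrame({
        "gene": genes[expressed],
        "species": species,
        "organ": organ,
        "lfc": lfc[expressed],
        "p": p[expressed],
    })
    out["padj"] = bh_adjust(out["p"].to_numpy())
    sig = out["padj"] < alpha
    out["direction"] = "unbiased"
    out.loc[sig & (out["lfc"] > lfc_threshold), "direction"] = "MBG"
    out.loc[sig & (out["lfc"] < -lfc_threshold), "direction"] = "FBG"
    out["category"] = "none"
    biased = out["direction"] != "unbiased"
    out.loc[biased, "category"] = out.loc[biased, "lfc"].map(assign_bias_category)
    return out.reset_index(drop=True)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_all_sex_bias(norm_counts: pd.DataFrame, metadata: pd.DataFrame,
                      min_reps: int = 2, **kw) -> pd.DataFrame:
    """Run ``test_sex_bias`` for every species×organ with enough replicates.

    Contrasts lacking ``min_reps`` replicates of either sex are skipped (the
    skip is recorded in the returned frame's ``attrs['skipped']``).
    """
    tables, skipped = [], []
    for (sp, org), grp in metadata.groupby(["species", "organ"]):
        n_m = (grp["sex"] == "M").sum()
        n_f = (grp["sex"] == "F").sum()
        if n_m < min_reps or n_f < min_reps:
            skipped.append((sp, org, f"{n_m}M/{n_f}F"))
            continue
        tables.append(test_sex_bias(norm_counts, metadata, sp, org,
                                    min_reps=min_reps, **kw))
    out = (pd.concat(tables, ignore_index=True) if tables
           else pd.DataFrame(columns=["gene", "species", "organ", "lfc", "p",
                                      "padj", "direction", "category"]))
    out.attrs["skipped"] = skipped
    return out


def shared_sbg_sets(bias_table: pd.DataFrame) -> pd.DataFrame:
    """Cross-species sharing of SBG status, per organ and direction.

    A gene is "shared" when biased in the same direction in ≥2 species of the
    same organ and "species-specific" when in exactly 1. Returns per
    (organ, direction): n_shared, n_specific and the shared fraction.
    """
    rows = []
    biased = bias_table[bias_table["direction"].isin(["MBG", "FBG"])]
    for (organ, direction), grp in biased.groupby(["organ", "direction"]):
        per_gene = grp.groupby("gene")["species"].nunique()
        shared = int((per_gene >= 2).sum())
        specific = int((per_gene == 1).sum())
        total = shared + specific
        rows.append((organ, direction, shared, specific,
                     shared / total if total else math.nan))
    return pd.DataFrame(rows, columns=["organ", "direction", "n_shared",
                                       "n_specific", "fraction_shared"])


def expression_variance_check(bias_table: pd.DataFrame,
                              norm_counts: pd.DataFrame,
                              metadata: pd.DataFrame) -> pd.DataFrame:
    """Correlate SBG counts with within-replicate expression variance.

    For each species×organ the variance summary is the median over genes and
    sexes of the per-gene variance of TMM-normalized counts. Reports Spearman
    ρ (average-rank ties) and p, overall and per organ; ρ is nan when either
    vector is constant, p is nan with <3 points.
    """
    md = metadata.set_index("sample")
    recs = []
    for (sp, org), grp in md.groupby(["species", "organ"]):
        n_sbg = len(bias_table[(bias_table["species"] == sp)
                               & (bias_table["organ"] == org)
                               & (bias_table["direction"] != "unbiased")])
        variances = []
        for sex in ("M", "F"):
            cols = [s for s in grp[grp["sex"] == sex].index
                    if s in norm_counts.columns]
            if len(cols) >= 2:
                variances.append(norm_counts[cols].var(axis=1, ddof=1))
        if not variances:
            continue
        recs.append((sp, org, n_sbg, float(pd.concat(variances).median())))
    pts = pd.DataFrame(recs, columns=["species", "organ", "n_sbg", "median_var"])
    rows = []
    for label, sub in [("overall", pts)] + [(o, g) for o, g in pts.groupby("organ")]:
        if len(sub) < 2 or sub["median_var"].nunique() == 1 or sub["n_sbg"].nunique() == 1:
            rows.append((label, len(sub), math.nan, math.nan))
            continue
        rho, p = stats.spearmanr(sub["n_sbg"], sub["median_var"])
        rows.append((label, len(sub), float(rho),
                     float(p) if len(sub) >= 3 else math.nan))
    return pd.DataFrame(rows, columns=["scope", "n_points", "rho", "p"])
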