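"""Sequence- and expression-level selection statistics.

Pairwise dN/dS per gene is computed by Nei–Gojobori (1986) counting against
the reference orthologue: synonymous/nonsynonymous site counts by per-codon
mutation-fate enumeration (stop-codon mutants excluded), observed differences
averaged over all shortest substitution paths, and a Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)·p) on both proportions. Selection on expression is
the standardized shift Δx of a focal species from the reference (ancestral
proxy) species on log2(TPM+1); |Δx| > 1 flags putative directional selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = ["DnDsResult", "ng86_dnds", "delta_x", "tpm_from_counts",
           "joint_candidates"]

_BASES = "ACGT"
_FORWARD = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for a stop codon."""
    return None if codon in _STOPS else _FORWARD[codon]


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (mutations to stops excluded)."""
    aa0 = _aa(codon)
    total = 0.0
    for i in range(3):
        syn = nonsyn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut in _STOPS:
                continue
            if _aa(mut) == aa0:
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn:
            total += syn / (syn + nonsyn)
    return total


_SYN_SITES = {c: _codon_syn_sites(c)
              for c in map("".join, itertools.product(_BASES, repeat=3))
              if c not in _STOPS}


def _path_counts(a: str, b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) differences between two codons over all shortest
    substitution paths; paths through stop codons are dropped when any
    stop-free path exists."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if nxt in _STOPS and nxt != b:
                through_stop = True
            if _aa(cur) == _aa(nxt) and _aa(cur) is not None:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [p for p in paths if not p[2]]
    use = clean or paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; nan when saturated (p ≥ 3/4)."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """Pairwise NG86 result: site counts, observed differences, corrected
    rates and their ratio (nan when dS is 0 or a correction saturates)."""

    n_codons: int
    N: float
    S_sites: float
    Nd: float
    Sd: float
    dN: float
    dS: float
    omega: float


def ng86_dnds(seq_a: str, seq_b: str) -> DnDsResult:
    """NG86 pairwise dN/dS between two in-frame aligned coding sequences.

    Sequences must have equal length, a multiple of 3, and no internal stop
    codons; codons containing a gap or ambiguity character in either
    sequence are deleted pairwise.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} not a multiple of 3")
    N = S_sites = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            if i + 3 < len(a):
                raise ValueError(f"internal stop codon at position {i + 1}")
            continue
        n_codons += 1
        s = (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        S_sites += s
        N += 3.0 - s
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S_sites if S_sites > 0 else 0.0
    dN = _jc(pN)
    dS = _jc(pS)
    if dN == 0.0 and Sd > 0:
        omega = 0.0  # no nonsynonymous change: ω = 0 even at saturated dS
    elif math.isnan(dN) or math.isnan(dS) or dS == 0.0:
        omega = math.nan
    else:
        omega = dN / dS
    return DnDsResult(n_codons, N, S_sites, Nd, Sd, dN, dS, omega)


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and per-gene lengths (bp)."""
    L = lengths.reindex(counts.index)
    if L.isna().any():
        raise ValueError(f"missing lengths for genes: "
                         f"{list(L.index[L.isna()])[:5]}")
    rate = counts.div(L / 1e3, axis=0)
    return rate / rate.sum(axis=0) * 1e6


def delta_x(expr_focal, expr_ref, *, denominator: str = "pooled") -> tuple[float, str]:
    """Standardized expression shift of a focal species from the reference.

    Δx = (mean(log2(TPM_focal+1)) − mean(log2(TPM_ref+1))) / SD, with the SD
    pooled over both species' replicates (``denominator='focal'`` uses the
    focal SD only). Returns (Δx, direction) with direction ``over`` for
    Δx > 1, ``under`` for Δx < −1, else ``none``. A zero SD gives Δx = 0
    when the means agree and nan otherwise. Needs ≥2 replicates per species.
    """
    f = np.log2(np.asarray(expr_focal, dtype=float) + 1.0)
    r = np.log2(np.asarray(expr_ref, dtype=float) + 1.0)
    if f.size < 2 or r.size < 2:
        return math.nan, "none"
    diff = f.mean() - r.mean()
    if denominator == "pooled":
        sd = math.sqrt(((f.size - 1) * f.var(ddof=1) + (r.size - 1) * r.var(ddof=1))
                       / (f.size + r.size - 2))
    elif denominator == "focal":
        sd = f.std(ddof=1)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if sd == 0.0:
        dx = 0.0 if diff == 0.0 else math.nan
    else:
        dx = diff / sd
    if not math.isnan(dx) and dx > 1:
        direction = "over"
    elif not math.isnan(dx) and dx < -1:
        direction = "under"
    else:
        direction = "none"
    return float(dx), direction


def delta_x_table(tpm: pd.DataFrame, metadata: pd.DataFrame, focal: str,
                  reference: str, *, organs=None) -> pd.DataFrame:
    """Vectorized Δx for every gene of a focal species against the reference.

    Replicates of both sexes within each organ are pooled as the species'
    expression sample. Returns gene, species, organ, delta_x, direction.
    """
    md = metadata.set_index("sample")
    organs = organs if organs is not None else sorted(md["organ"].unique())
    out = []
    for organ in organs:
        cols_f = md[(md["species"] == focal) & (md["organ"] == organ)].index
        cols_r = md[(md["species"] == reference) & (md["organ"] == organ)].index
        cols_f = [c for c in cols_f if c in tpm.columns]
        cols_r = [c for c in cols_r if c in tpm.columns]
        if len(cols_f) < 2 or len(cols_r) < 2:
            continue
        F = np.log2(tpm[cols_f].to_numpy(dtype=float) + 1.0)
        R = np.log2(tpm[cols_r].to_numpy(dtype=float) + 1.0)
        nf, nr = F.shape[1], R.shape[1]
        diff = F.mean(1) - R.mean(1)
        pooled = np.sqrt(((nf - 1) * F.var(1, ddof=1)
                          + (nr - 1) * R.var(1, ddof=1)) / (nf + nr - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            dx = diff / pooled
        dx[(pooled == 0) & (diff == 0)] = 0.0
        direction = np.where(dx > 1, "over", np.where(dx < -1, "under", "none"))
        out.append(pd.DataFrame({
            "gene": tpm.index, "species": focal, "organ": organ,
            "delta_x": dx, "direction": direction,
        }))
    if not out:
        return pd.DataFrame(columns=["gene", "species", "organ", "delta_x",
                                     "direction"])
    return pd.concat(out, ignore_index=True)


def joint_candidates(deltax_table: pd.DataFrame, dnds_table: pd.DataFrame,
                     dnds_cut: float = 1.0, deltax_cut: float = 1.0) -> pd.DataFrame:
    """Genes under putative selection at both levels, per species.

    Keeps (gene, species) pairs with |Δx| > ``deltax_cut`` in some organ and
    ω > ``dnds_cut``; the Δx table needs columns gene, species, organ,
    delta_x and the dN/dS table gene, species, omega.
    """
    dx = deltax_table[deltax_table["delta_x"].abs() > deltax_cut]
    dn = dnds_table[dnds_table["omega"] > dnds_cut]
    merged = dx.merge(dn[["gene", "species", "omega"]], on=["gene", "species"])
    cols = [c for c in ("species", "lg", "gene", "organ", "delta_x", "omega")
            if c in merged.columns]
    return merged[cols].sort_values(["species", "gene"]).reset_index(drop=True)
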