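"""Population-genetic statistics: worked values, brute-force oracles and
invariances."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbgevo import popgen


# ---------------------------------------------------------------------------
# Hudson alpha/beta and the ratio-of-sums aggregation

@pytest.mark.parametrize("p1,n1,p2,n2,alpha,beta", [
    (1.0, 10, 0.0, 10, 1.0, 1.0),                  # fixed difference
    (0.5, 10, 0.5, 10, -1.0 / 18.0, 0.5),          # identical frequencies
    (0.5, 10, 0.0, 10, 0.25 - 0.25 / 9.0, 0.5),    # XY-divergent site pattern
])
def test_hudson_alpha_beta_worked_values(p1, n1, p2, n2, alpha, beta):
    a, b = popgen.hudson_alpha_beta(p1, n1, p2, n2)
    assert a == pytest.approx(alpha, abs=1e-12)
    assert b == pytest.approx(beta, abs=1e-12)


def test_hudson_symmetry_and_errors():
    a1, b1 = popgen.hudson_alpha_beta(0.3, 8, 0.7, 12)
    a2, b2 = popgen.hudson_alpha_beta(0.7, 12, 0.3, 8)
    assert a1 == pytest.approx(a2) and b1 == pytest.approx(b2)
    with pytest.raises(ValueError):
        popgen.hudson_alpha_beta(0.5, 1, 0.5, 10)


def test_gene_fst_ratio_of_sums():
    # arithmetic oracle: {(1,1), (-0.0556,0.5)} -> 0.9444/2.4444
    fst = popgen.gene_fst_ratio_of_sums([1.0, -1 / 18], [1.0, 0.5])
    assert fst == pytest.approx((1 - 1 / 18) / (2.5 - 1 / 18), abs=1e-12)
    # a fully fixed difference: alpha = beta = 1 per site
    assert popgen.gene_fst_ratio_of_sums([1.0], [1.0]) == 0.5
    assert math.isnan(popgen.gene_fst_ratio_of_sums([], []))
    # the divergent-site example: per-site ratio 0.2222/0.7222 ~ 0.3077
    a, b = popgen.hudson_alpha_beta(0.5, 10, 0.0, 10)
    assert popgen.gene_fst_ratio_of_sums([a], [b]) == pytest.approx(0.30769, abs=1e-4)


# ---------------------------------------------------------------------------
# site and gene diversity

def brute_force_site_pi(d, n):
    """Fraction of haplotype pairs differing at the site, by enumeration."""
    hap = [1] * d + [0] * (n - d)
    pairs = list(itertools.combinations(range(n), 2))
    return sum(hap[i] != hap[j] for i, j in pairs) / len(pairs)


@pytest.mark.parametrize("d,n", [(0, 4), (2, 4), (1, 10), (5, 10), (9, 10)])
def test_site_pi_matches_pairwise_enumeration(d, n):
    assert popgen.site_pi(d, n) == pytest.approx(brute_force_site_pi(d, n),
                                                 abs=1e-12)


def test_site_pi_symmetry_and_maximum():
    for n in (4, 10):
        for d in range(n + 1):
            assert popgen.site_pi(d, n) == pytest.approx(popgen.site_pi(n - d, n))
        assert max(popgen.site_pi(d, n) for d in range(n + 1)) == \
            popgen.site_pi(n // 2, n)


def test_gene_pi_corrected():
    assert popgen.gene_pi_corrected([1.6667], 100) == pytest.approx(0.016667)
    assert popgen.gene_pi_corrected([], 50) == 0.0
    num = [0.5, 0.5]
    assert popgen.gene_pi_corrected(num, 50) == pytest.approx(
        2 * popgen.gene_pi_corrected(num, 100))


# ---------------------------------------------------------------------------
# Tajima's D

def tajimas_d_reference(derived_counts, n):
    """Independent evaluation of the 1989 formulas, written from scratch."""
    S = len(derived_counts)
    pi = sum(2 * d * (n - d) / (n * (n - 1)) for d in derived_counts)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_worked_value():
    pis = [popgen.site_pi(d, 4) for d in (1, 1, 2)]
    d = popgen.tajimas_d(3, pis, 4)
    assert d == pytest.approx(0.168, abs=5e-4)
    assert d == pytest.approx(tajimas_d_reference([1, 1, 2], 4), abs=1e-12)


def test_tajimas_d_singleton_excess_negative():
    n, S = 20, 40
    pis = [popgen.site_pi(1, n)] * S
    assert popgen.tajimas_d(S, pis, n) < 0


def test_tajimas_d_undefined_when_no_variants():
    assert math.isnan(popgen.tajimas_d(0, [], 10))


def test_tajimas_d_neutral_coalescent_centred_near_zero():
    """Under neutral coalescent simulations D should be centred near 0."""
    msprime = pytest.importorskip("msprime")
    vals = []
    for rep, ts in enumerate(msprime.sim_ancestry(
            samples=10, ploidy=2, sequence_length=2000,
            population_size=1000, num_replicates=200, random_seed=5)):
        mts = msprime.sim_mutations(ts, rate=2e-7, random_seed=rep + 1)
        n = mts.num_samples
        counts = [int(v.genotypes.sum()) for v in mts.variants()]
        counts = [c for c in counts if 0 < c < n]
        if not counts:
            continue
        pis = [popgen.site_pi(c, n) for c in counts]
        vals.append(popgen.tajimas_d(len(counts), pis, n))
    assert len(vals) > 150
    assert abs(np.mean(vals)) < 0.3


# ---------------------------------------------------------------------------
# site filters and SFS

def _site_row(n_cov, depth, n_m, n_f, **kw):
    base = dict(lg="LG1", pos=kw.pop("pos", 1), n_covered=n_cov,
                total_depth=depth, n_covered_male=n_m, n_covered_female=n_f)
    base.update(kw)
    return base


def test_apply_site_filters_rules():
    sites = pd.DataFrame([
        _site_row(2, 10, 1, 1, pos=1),   # <3 individuals: dropped everywhere
        _site_row(3, 10, 1, 2, pos=2),   # 1 male: general only
        _site_row(3, 2, 2, 1, pos=3),    # depth <3: dropped
        _site_row(6, 40, 3, 3, pos=4),   # fully covered: both streams
    ])
    out = popgen.apply_site_filters(sites)
    assert out["pos"].tolist() == [2, 4]
    assert out.set_index("pos")["fst_eligible"].to_dict() == {2: False, 4: True}


def test_apply_site_filters_quality_column():
    sites = pd.DataFrame([
        _site_row(5, 30, 2, 3, pos=1, qual=12.0),
        _site_row(5, 30, 2, 3, pos=2, qual=13.0),
    ])
    assert popgen.apply_site_filters(sites)["pos"].tolist() == [2]


def test_build_sfs():
    sfs = popgen.build_sfs([1, 1, 2], 4)
    assert sfs.tolist() == [0, 2, 1, 0, 0]
    folded = popgen.build_sfs([3], 4, folded=True)
    assert folded.tolist() == [0, 1, 0]
    sym = popgen.build_sfs([1, 3, 2], 4, folded=True)
    assert sym.sum() == 3


# ---------------------------------------------------------------------------
# gene-level aggregation vs brute force from raw genotypes

def brute_force_gene_stats(genotypes_m, genotypes_f):
    """Per-gene Fst/pi/D straight from diploid genotype lists (<=10 sites).

    genotypes_*: list over sites of lists of diploid genotypes (0/1/2 alt
    copies), no missing data.
    """
    alphas, betas, pis, counts = [], [], [], []
    for gm, gf in zip(genotypes_m, genotypes_f):
        n1, n2 = 2 * len(gm), 2 * len(gf)
        d1, d2 = sum(gm), sum(gf)
        p1, p2 = d1 / n1, d2 / n2
        a = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        b = p1 * (1 - p2) + p2 * (1 - p1)
        n, d = n1 + n2, d1 + d2
        if 0 < d < n:
            alphas.append(a)
            betas.append(b)
            pis.append(2 * d * (n - d) / (n * (n - 1)))
            counts.append(d)
    fst = sum(alphas) / sum(a + b for a, b in zip(alphas, betas))
    n_sites = len(genotypes_m)
    pi = sum(pis) / n_sites
    taj = tajimas_d_reference(counts, 2 * (len(genotypes_m[0]) + len(genotypes_f[0])))
    return fst, pi, taj


def test_gene_stats_table_matches_brute_force(rng):
    n_m = n_f = 4
    n_sites = 10
    gm = [list(rng.integers(0, 3, n_m)) for _ in range(n_sites)]
    gf = [list(rng.integers(0, 3, n_f)) for _ in range(n_sites)]
    # ensure at least one variant
    gm[0] = [1, 0, 0, 0]
    gf[0] = [0, 0, 0, 0]
    rows = []
    for i, (m, f) in enumerate(zip(gm, gf)):
        n_all = 2 * (n_m + n_f)
        d_all = sum(m) + sum(f)
        rows.append(dict(lg="LG1", pos=i + 1, n_covered=n_m + n_f,
                         total_depth=80, n_covered_male=n_m,
                         n_covered_female=n_f, fst_eligible=True,
                         n_all=n_all, d_all=d_all,
                         n_male=2 * n_m, d_male=sum(m),
                         n_female=2 * n_f, d_female=sum(f)))
    sites = pd.DataFrame(rows)
    ann = pd.DataFrame([("g1", "LG1", 1, n_sites)],
                       columns=["gene", "lg", "start", "end"])
    out = popgen.gene_stats_table(sites, ann).iloc[0]
    fst, pi, taj = brute_force_gene_stats(gm, gf)
    assert out["fst"] == pytest.approx(fst, abs=1e-10)
    assert out["pi"] == pytest.approx(pi, abs=1e-10)
    assert out["tajimas_d"] == pytest.approx(taj, abs=1e-10)
    assert out["n_covered"] == n_sites


@settings(deadline=None, max_examples=50)
@given(st.integers(2, 30).flatmap(
    lambda n: st.tuples(st.just(n), st.integers(0, 2 * n), st.integers(0, 2 * n))))
def test_fst_site_ratio_bounded_at_fixed_difference(args):
    """Site-level alpha <= beta-normalized bound: ratio never exceeds 1."""
    n, d1, d2 = args
    a, b = popgen.hudson_alpha_beta(d1 / (2 * n), 2 * n, d2 / (2 * n), 2 * n)
    if a + b > 0:
        assert a / (a + b) <= 1.0 + 1e-12
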