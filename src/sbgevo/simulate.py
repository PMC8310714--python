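"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a comparative RNA-seq study of a species radiation:
an ultrametric (Yule) species tree; per species two sexes × several organs ×
replicated negative-binomial counts whose log2 means drift as Brownian
motion along the tree; planted sex-biased genes whose bias state (U/FBG/MBG)
evolves on the tree under the same equal-rates Markov process the analysis
fits; per-individual genotypes with a neutral-like frequency spectrum on
autosomes and an XY-linked region where males are heterozygous for X/Y
divergent alleles; in-frame coding-sequence pairs with controlled dN/dS; and
per-species traits with a Brownian component. Every planted signal is
recorded in truth tables, and a fixed seed makes all outputs byte-identical.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .ancestral import STATES, transition_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_bias_states",
    "simulate_expression_counts",
    "simulate_genotypes",
    "simulate_coding_sequences",
    "simulate_traits",
    "simulate_dataset",
    "write_dataset",
]

_CATEGORY_RANGES = {
    "low": (2.05, 2.6),
    "mid": (2.6, 4.1),
    "high": (4.1, 6.5),
    "extreme": (6.5, 9.0),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Sizes mirror the study design (14 taxa, 5 organs, 3 replicates per sex
    and organ, ~10 Myr tree height) with the gene and site counts scaled to
    desk size. Rates are per Myr on the log2-expression scale.
    """

    n_species: int = 14
    tree_mode: str = "yule"  # or "fixed_newick"
    fixed_newick: str | None = None
    tree_height: float = 10.0
    organs: tuple[str, ...] = ("gonad", "brain", "liver", "gill", "jaw")
    replicates_per_sex_organ: int = 3
    n_genes: int = 800
    nb_dispersion: float = 0.05
    dispersion_sdlog: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    brownian_rate_per_organ: dict | float = 0.02
    sbg_rate_multiplier: float = 3.0
    sbg_fraction_per_organ: dict | float = field(
        default_factory=lambda: {"gonad": 0.4, "brain": 0.01, "liver": 0.01,
                                 "gill": 0.01, "jaw": 0.01})
    sbg_lfc_distribution: dict = field(
        default_factory=lambda: {"low": 0.35, "mid": 0.35, "high": 0.2,
                                 "extreme": 0.1})
    bias_state_rate: float = 0.02  # q of the equal-rates process on the tree
    library_size_cv: float = 0.3
    # genotypes
    n_individuals_per_sex: int = 5
    n_sites_per_gene: int = 40
    theta: float = 0.02
    mean_depth: float = 8.0
    coverage_dropout: float = 0.1
    n_lgs: int = 6
    xy_lg_index: int = 5          # 0-based index into the LG list
    xy_fraction_of_lg: float = 0.4
    xy_divergent_fraction: float = 0.5
    # probability that an XY-region SBG is male-biased at the root
    # (< 0.5 emulates demasculinization of the differentiated region)
    xy_mbg_probability: float = 0.05
    # coding sequences
    n_codons_per_gene: int = 120
    subst_rate: float = 0.06      # expected substitutions per nucleotide site
    omega_meanlog: float = math.log(0.2)
    omega_sdlog: float = 0.5
    n_positive_selection: int = 20
    omega_positive: float = 1.8
    deltax_shift: float = 3.0     # planted log2 shift for positive-selection genes
    deltax_focal_index: int = 1   # species index receiving the shift
    trait_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.tree_mode not in ("yule", "fixed_newick"):
            raise ValueError(f"unknown tree_mode {self.tree_mode!r}")
        if self.replicates_per_sex_organ < 2:
            raise ValueError("need at least two replicates per sex and organ")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        fracs = self.sbg_fraction_per_organ
        vals = fracs.values() if isinstance(fracs, dict) else [fracs]
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("sbg fractions must lie in [0, 1]")
        if not 0 <= self.coverage_dropout <= 1:
            raise ValueError("coverage_dropout must lie in [0, 1]")

    def organ_rate(self, organ: str) -> float:
        r = self.brownian_rate_per_organ
        return r[organ] if isinstance(r, dict) else float(r)

    def organ_sbg_fraction(self, organ: str) -> float:
        f = self.sbg_fraction_per_organ
        return f[organ] if isinstance(f, dict) else float(f)

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    @property
    def lg_names(self) -> list[str]:
        return [f"LG{i + 1}" for i in range(self.n_lgs)]

    @property
    def xy_lg(self) -> str:
        return self.lg_names[self.xy_lg_index]


@dataclass
class SimulatedDataset:
    """Container tying together all generated tables and the truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    counts: pd.DataFrame
    metadata: pd.DataFrame
    annotation: pd.DataFrame
    genotypes: dict
    sequences: dict
    traits: pd.DataFrame
    truth: dict


def simulate_tree(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Ultrametric species tree: fixed newick or a pure-birth (Yule) draw
    rescaled to the configured height. Tips are labelled sp01..spNN in the
    Yule case."""
    if config.tree_mode == "fixed_newick":
        if not config.fixed_newick:
            raise ValueError("tree_mode=fixed_newick needs fixed_newick")
        return dendropy.Tree.get(data=config.fixed_newick, schema="newick")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_species
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    # active lineages: (node, birth_time); root splits at time 0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    T = t + rng.exponential(1.0 / n)
    tns = dendropy.TaxonNamespace()
    labels = iter(config.species_names)  # lineage creation order
    for node, birth in active:
        node.edge.length = T - birth
        node.taxon = tns.new_taxon(next(labels))
    tree.taxon_namespace = tns
    scale = config.tree_height / T
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return tree


def _tree_covariance(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    from .ancestral import brownian_covariance
    return brownian_covariance(tree, species)


def simulate_bias_states(tree: dendropy.Tree, n_genes: int, q: float,
                         rng: np.random.Generator,
                         root_states: np.ndarray | None = None) -> pd.DataFrame:
    """Evolve 3-state (U/FBG/MBG) characters down the tree at rate q.

    ``root_states`` are integer codes into STATES (uniform draw when None).
    Returns a gene×tip frame of state labels; the per-branch transition draw
    uses the equal-rates transition matrix over each branch length.
    """
    nodes = list(tree.preorder_node_iter())
    states: dict[int, np.ndarray] = {}
    if root_states is None:
        root_states = rng.integers(0, 3, size=n_genes)
    states[id(nodes[0])] = np.asarray(root_states, dtype=int)
    for node in nodes[1:]:
        parent = states[id(node.parent_node)]
        P = transition_matrix(q, node.edge.length or 0.0)
        u = rng.random(n_genes)
        cum = np.cumsum(P[parent], axis=1)
        states[id(node)] = (u[:, None] > cum).sum(axis=1)
    tips = {n.taxon.label: states[id(n)] for n in tree.leaf_node_iter()}
    return pd.DataFrame({sp: [STATES[s] for s in tips[sp]]
                         for sp in sorted(tips)})


def _make_annotation(config: SimulationConfig) -> pd.DataFrame:
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    span = config.n_sites_per_gene
    gap = 20
    rows = []
    for i, g in enumerate(genes):
        lg = config.lg_names[i % config.n_lgs]  # round robin: every LG filled
        j = i // config.n_lgs
        start = j * (span + gap) + 1
        rows.append((g, lg, start, start + span - 1))
    return pd.DataFrame(rows, columns=["gene", "lg", "start", "end"])


def _xy_gene_mask(config: SimulationConfig, annotation: pd.DataFrame) -> pd.Series:
    lg = config.xy_lg
    on_lg = annotation["lg"] == lg
    if not on_lg.any():
        raise ValueError(f"xy region LG {lg} not covered by annotation")
    lg_end = annotation.loc[on_lg, "end"].max()
    cutoff = lg_end * config.xy_fraction_of_lg
    return on_lg & (annotation["end"] <= cutoff)


def simulate_expression_counts(config: SimulationConfig, tree: dendropy.Tree,
                               rng: np.random.Generator | None = None,
                               annotation: pd.DataFrame | None = None):
    """Counts + metadata + truth for the expression stages.

    Per gene and organ a log2 baseline evolves as Brownian motion along the
    tree; genes whose evolved bias state at a tip is MBG (FBG) get the
    planted LFC added to the male (female) log2 mean there; counts are
    negative-binomial around 2^mean with gene-wise lognormal dispersion and
    lognormal library-size factors.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if annotation is None:
        annotation = _make_annotation(config)
    species = config.species_names
    genes = annotation["gene"].tolist()
    G, S = len(genes), len(species)
    C = _tree_covariance(tree, species)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(S))
    phi = rng.lognormal(math.log(config.nb_dispersion),
                        config.dispersion_sdlog, size=G)
    cv = config.library_size_cv
    sdlog_lib = math.sqrt(math.log(1.0 + cv * cv))
    cats = list(_CATEGORY_RANGES)
    cat_p = np.array([config.sbg_lfc_distribution[c] for c in cats])
    cat_p = cat_p / cat_p.sum()

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    deltax_rows = []
    focal_sp = species[config.deltax_focal_index % S]
    pos_genes = set(genes[:config.n_positive_selection])

    for organ in config.organs:
        rate = config.organ_rate(organ)
        frac = config.organ_sbg_fraction(organ)
        baseline = rng.normal(config.baseline_log2_mean,
                              config.baseline_log2_sd, size=G)
        capable = rng.random(G) < frac
        lfc = np.zeros(G)
        cat_choice = rng.choice(len(cats), size=G, p=cat_p)
        for ci, cname in enumerate(cats):
            lo, hi = _CATEGORY_RANGES[cname]
            sel = capable & (cat_choice == ci)
            lfc[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
        xy_genes = _xy_gene_mask(config, annotation).to_numpy()
        p_mbg = np.where(xy_genes, config.xy_mbg_probability, 0.5)
        root_dir = np.where(rng.random(G) < p_mbg, 2, 1)  # MBG or FBG code
        root_states = np.where(capable, root_dir, 0)
        state_df = simulate_bias_states(tree, G, config.bias_state_rate, rng,
                                        root_states=root_states)
        # Brownian species deviations; planted SBGs drift faster
        mult = np.where(capable, config.sbg_rate_multiplier, 1.0)
        z = rng.standard_normal((G, S))
        dev = (z @ L.T) * np.sqrt(rate * mult)[:, None]
        log2_mean = baseline[:, None] + dev  # G × S, sex-neutral component
        shift = np.array([config.deltax_shift if g in pos_genes else 0.0
                          for g in genes])
        for si, sp in enumerate(species):
            st = state_df[sp].map({"U": 0, "FBG": 1, "MBG": 2}).to_numpy()
            st = np.where(capable, st, 0)  # only planted genes carry bias
            male = log2_mean[:, si] + np.where(st == 2, lfc, 0.0)
            female = log2_mean[:, si] + np.where(st == 1, lfc, 0.0)
            if sp == focal_sp:
                male = male + shift
                female = female + shift
                for g in sorted(pos_genes):
                    deltax_rows.append((g, sp, organ, config.deltax_shift))
            for gi in np.flatnonzero(st != 0):
                truth_rows.append((genes[gi], sp, organ,
                                   "MBG" if st[gi] == 2 else "FBG",
                                   float(lfc[gi])))
            for sex, mu_log2 in (("M", male), ("F", female)):
                for rep in range(1, config.replicates_per_sex_organ + 1):
                    sid = f"{sp}_{organ}_{sex}{rep}"
                    lib = rng.lognormal(-0.5 * sdlog_lib**2, sdlog_lib)
                    mu = np.exp2(mu_log2) * lib
                    n_nb = 1.0 / phi
                    p_nb = n_nb / (n_nb + mu)
                    counts[sid] = rng.negative_binomial(n_nb, p_nb)
                    meta_rows.append((sid, sp, sex, organ, rep))
    count_df = pd.DataFrame(counts, index=genes)
    count_df.index.name = "gene"
    metadata = pd.DataFrame(meta_rows,
                            columns=["sample", "species", "sex", "organ",
                                     "replicate"])
    truth = pd.DataFrame(truth_rows,
                         columns=["gene", "species", "organ", "direction", "lfc"])
    deltax_truth = pd.DataFrame(deltax_rows,
                                columns=["gene", "species", "organ", "shift"])
    return count_df, metadata, truth, deltax_truth


def simulate_genotypes(config: SimulationConfig, annotation: pd.DataFrame,
                       rng: np.random.Generator | None = None) -> dict:
    """Diploid genotypes with depth for every species' individuals.

    Autosomal sites segregate with probability ≈ θ·a_n; derived sample
    counts follow the neutral 1/i spectrum and alleles are placed on
    chromosomes independently of sex. Sites in the XY region that are drawn
    "divergent" have every male heterozygous (X/Y) and every female
    homozygous X. Per-individual depth is Poisson with dropout; depth-0
    genotypes are missing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = config.species_names
    n_per_sex = config.n_individuals_per_sex
    n_ind = 2 * n_per_sex
    n_chrom = 2 * n_ind
    a_n = sum(1.0 / i for i in range(1, n_chrom))
    p_seg = min(1.0, config.theta * a_n)
    xy_mask_genes = _xy_gene_mask(config, annotation)
    site_lg, site_pos, site_xy = [], [], []
    for rec, is_xy in zip(annotation.itertuples(index=False), xy_mask_genes):
        for pos in range(rec.start, rec.end + 1):
            site_lg.append(rec.lg)
            site_pos.append(pos)
            site_xy.append(is_xy)
    n_sites = len(site_pos)
    site_xy = np.array(site_xy)
    weights = 1.0 / np.arange(1, n_chrom)
    weights /= weights.sum()

    individuals, sexes_all = [], []
    geno = {}
    depth = {}
    for sp in species:
        inds = [f"{sp}_M{i + 1}" for i in range(n_per_sex)] + \
               [f"{sp}_F{i + 1}" for i in range(n_per_sex)]
        sexes = np.array(["M"] * n_per_sex + ["F"] * n_per_sex)
        individuals += inds
        sexes_all += list(sexes)
        g = np.zeros((n_sites, n_ind, 2), dtype=np.int8)
        seg = rng.random(n_sites) < p_seg
        div = site_xy & (rng.random(n_sites) < config.xy_divergent_fraction)
        seg &= ~div
        seg_idx = np.flatnonzero(seg)
        k = rng.choice(np.arange(1, n_chrom), size=seg_idx.size, p=weights)
        for idx, ki in zip(seg_idx, k):
            chroms = rng.choice(n_chrom, size=ki, replace=False)
            g[idx, chroms // 2, chroms % 2] = 1
        male_cols = np.flatnonzero(sexes == "M")
        div_idx = np.flatnonzero(div)
        g[np.ix_(div_idx, male_cols)] = np.array([0, 1], dtype=np.int8)
        d = rng.poisson(config.mean_depth, size=(n_sites, n_ind))
        drop = rng.random((n_sites, n_ind)) < config.coverage_dropout
        d[drop] = 0
        geno[sp] = g
        depth[sp] = d
    return {
        "individuals": pd.DataFrame({
            "individual": individuals,
            "species": [i.rsplit("_", 1)[0] for i in individuals],
            "sex": sexes_all,
        }),
        "site_lg": np.array(site_lg),
        "site_pos": np.array(site_pos, dtype=int),
        "site_xy_divergent_eligible": site_xy,
        "genotypes": geno,
        "depth": depth,
    }


_BASES = "ACGT"
_STOP = {"TAA", "TAG", "TGA"}
_CODONS = [c for c in map("".join, itertools.product(_BASES, repeat=3))
           if c not in _STOP]

_AA = None


def _codon_aa(codon: str) -> str:
    global _AA
    if _AA is None:
        from Bio.Data.CodonTable import standard_dna_table
        _AA = dict(standard_dna_table.forward_table)
    return _AA[codon]


def simulate_coding_sequences(config: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              genes: list[str] | None = None,
                              omegas: np.ndarray | None = None) -> dict:
    """Per-gene (reference, derived) in-frame codon sequence pairs.

    The derived sequence accumulates Poisson-many single-nucleotide
    proposals; synonymous changes are accepted with probability min(1, 1/ω)
    and nonsynonymous with min(1, ω), so the realized dN/dS targets ω.
    Changes creating stop codons are rejected. Truth records ω per gene.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if genes is None:
        genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    G = len(genes)
    if omegas is None:
        omegas = rng.lognormal(config.omega_meanlog, config.omega_sdlog, size=G)
        omegas[:config.n_positive_selection] = config.omega_positive
    pairs = {}
    n_nt = 3 * config.n_codons_per_gene
    for g, omega in zip(genes, omegas):
        ref_codons = [
            _CODONS[i] for i in rng.integers(0, len(_CODONS),
                                             size=config.n_codons_per_gene)
        ]
        seq = list("".join(ref_codons))
        n_prop = rng.poisson(config.subst_rate * n_nt)
        acc_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        acc_non = min(1.0, omega)
        for _ in range(n_prop):
            pos = int(rng.integers(n_nt))
            old = seq[pos]
            new = _BASES[int(rng.integers(4))]
            if new == old:
                continue
            c0 = pos - pos % 3
            codon_old = "".join(seq[c0:c0 + 3])
            codon_new = codon_old[:pos - c0] + new + codon_old[pos - c0 + 1:]
            if codon_new in _STOP:
                continue
            if _codon_aa(codon_new) == _codon_aa(codon_old):
                accept = acc_syn
            else:
                accept = 0.0 if omega == 0 else acc_non
            if rng.random() < accept:
                seq[pos] = new
        pairs[g] = ("".join(ref_codons), "".join(seq))
    truth = pd.DataFrame({"gene": genes, "omega": omegas})
    return {"pairs": pairs, "truth": truth}


def simulate_traits(config: SimulationConfig, tree: dendropy.Tree,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-species traits: Brownian component on the tree plus noise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = config.species_names
    C = _tree_covariance(tree, species)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(species)))
    names = ["sperm_competition_rank", "sexual_dimorphism",
             "sexchr_differentiation"]
    data = {}
    for name in names:
        bm = L @ rng.standard_normal(len(species))
        data[name] = bm / math.sqrt(config.tree_height) + \
            rng.normal(0.0, config.trait_noise_sd, len(species))
    out = pd.DataFrame(data, index=species)
    out.index.name = "species"
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full labelled dataset from a single seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    annotation = _make_annotation(config)
    counts, metadata, sbg_truth, deltax_truth = simulate_expression_counts(
        config, tree, rng, annotation)
    genotypes = simulate_genotypes(config, annotation, rng)
    sequences = simulate_coding_sequences(config, rng,
                                          genes=annotation["gene"].tolist())
    traits = simulate_traits(config, tree, rng)
    xy_genes = annotation.loc[_xy_gene_mask(config, annotation), "gene"].tolist()
    truth = {
        "sbg": sbg_truth,
        "deltax_shifts": deltax_truth,
        "omega": sequences["truth"],
        "xy_genes": xy_genes,
        "bias_state_rate": config.bias_state_rate,
    }
    return SimulatedDataset(config=config, tree=tree, counts=counts,
                            metadata=metadata, annotation=annotation,
                            genotypes=genotypes, sequences=sequences,
                            traits=traits, truth=truth)


# ---------------------------------------------------------------------------
# writers

def _write_vcf(path: Path, genotypes: dict) -> None:
    inds = genotypes["individuals"]["individual"].tolist()
    lgs = genotypes["site_lg"]
    poss = genotypes["site_pos"]
    species = list(genotypes["genotypes"])
    # vectorized cell strings per species, then row-wise join
    cell_blocks = []
    for sp in species:
        g = genotypes["genotypes"][sp]
        d = genotypes["depth"][sp]
        gt = np.char.add(
            np.char.add(g[:, :, 0].astype("U1"), "/"), g[:, :, 1].astype("U1"))
        cells = np.char.add(np.char.add(gt, ":"), d.astype("U6"))
        cells[d == 0] = "./.:0"
        cell_blocks.append(cells)
    all_cells = np.concatenate(cell_blocks, axis=1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for lg in sorted(set(lgs)):
            fh.write(f"##contig=<ID={lg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        for i in range(len(poss)):
            fh.write(f"{lgs[i]}\t{poss[i]}\t.\tA\tG\t60\tPASS\t.\tGT:DP\t"
                     + "\t".join(all_cells[i]) + "\n")


def _write_gff3(path: Path, annotation: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.itertuples(index=False):
            fh.write(f"{r.lg}\tsbgevo\tgene\t{r.start}\t{r.end}\t.\t+\t.\t"
                     f"ID={r.gene}\n")


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict:
    """Write every table of a simulated dataset as plain-text files.

    Returns the file manifest (name → path). Output is byte-identical for a
    fixed config and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def save(df: pd.DataFrame, name: str, **kw):
        p = out / name
        df.to_csv(p, sep="\t", float_format="%.6g", **kw)
        files[name] = str(p)

    save(ds.counts, "counts.tsv", index=True)
    save(ds.metadata, "metadata.tsv", index=False)
    save(ds.annotation, "annotation.tsv", index=False)
    _write_gff3(out / "annotation.gff3", ds.annotation)
    files["annotation.gff3"] = str(out / "annotation.gff3")
    _write_vcf(out / "genotypes.vcf", ds.genotypes)
    files["genotypes.vcf"] = str(out / "genotypes.vcf")
    save(ds.genotypes["individuals"], "individuals.tsv", index=False)
    ds.tree.write(path=str(out / "species_tree.nwk"), schema="newick",
                  suppress_rooting=True)
    files["species_tree.nwk"] = str(out / "species_tree.nwk")
    save(ds.traits, "traits.tsv", index=True)
    save(ds.truth["sbg"], "truth_sbg.tsv", index=False)
    save(ds.truth["omega"], "truth_omega.tsv", index=False)
    save(ds.truth["deltax_shifts"], "truth_deltax.tsv", index=False)
    with open(out / "cds_pairs.fasta", "w") as fh:
        for g, (ref, der) in ds.sequences["pairs"].items():
            fh.write(f">{g}|ref\n{ref}\n>{g}|derived\n{der}\n")
    files["cds_pairs.fasta"] = str(out / "cds_pairs.fasta")
    manifest = {
        "seed": ds.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(ds.config).items()},
        "files": sorted(files),
        "xy_genes": ds.truth["xy_genes"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    files["manifest.json"] = str(out / "manifest.json")
    return files
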