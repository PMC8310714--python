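"""End-to-end pipeline driver over synthetic or user-supplied data.

Stages run in dependency order: simulate → de → popgen → molevol → exprtree
→ ancestral → enrich. Every output table carries the config hash in a
comment header, and a manifest with per-file checksums is written at the
end; a fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import ancestral, de, exprtree, genomedist, io, molevol, popgen
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger("sbgevo")

ALL_STAGES = ("simulate", "de", "popgen", "molevol", "exprtree",
              "ancestral", "enrich")


@dataclass
class PipelineConfig:
    outdir: str
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = ALL_STAGES
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    min_reps: int = 2
    deltax_cut: float = 1.0
    dnds_cut: float = 1.0
    n_boot: int = 200
    enrich_organ: str = "gonad"

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # the analysis, not its location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def basal_taxon(tree: dendropy.Tree) -> str:
    """The most basal tip: fewest internal nodes on its root path (ties by
    label) — the outgroup used for rooting and as the Δx reference."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0, leaf
        while node.parent_node is not None:
            d += 1
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return min(sorted(depths), key=depths.get)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    out = Path(config.outdir)
    res = out / "results"
    res.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    written: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = False):
        path = res / name
        io.write_table(df, path, config_hash=h, index=index)
        written[f"results/{name}"] = _sha256(path)

    # ---- simulate -------------------------------------------------------
    data_dir = out / "data"
    if "simulate" in config.stages:
        log.info("simulate: generating dataset (seed=%d)", config.sim.seed)
        ds = simulate_dataset(config.sim)
        files = write_dataset(ds, data_dir)
        for name, path in files.items():
            written[f"data/{name}"] = _sha256(path)
    if not data_dir.exists():
        raise FileNotFoundError(f"no input data under {data_dir}")

    counts = io.read_counts(data_dir / "counts.tsv")
    metadata = io.read_metadata(data_dir / "metadata.tsv")
    annotation = io.read_annotation(data_dir / "annotation.gff3")
    tree = io.read_tree(data_dir / "species_tree.nwk")
    traits = io.read_traits(data_dir / "traits.tsv")
    outgroup = basal_taxon(tree)

    # ---- differential expression ---------------------------------------
    bias = None
    norm = None
    if "de" in config.stages:
        filtered = de.filter_low_count_genes(counts)
        log.info("de: %d/%d genes pass the count filter",
                 len(filtered), len(counts))
        norm = de.tmm_normalize(filtered)
        flags = de.qc_flag_samples(filtered, metadata)
        emit(flags, "qc_flags.tsv")
        bias = de.call_all_sex_bias(norm, metadata, min_reps=config.min_reps,
                                    alpha=config.alpha,
                                    lfc_threshold=config.lfc_threshold)
        for sp, organ, why in bias.attrs.get("skipped", []):
            log.info("de: skipped %s/%s (%s)", sp, organ, why)
        emit(bias, "sex_bias.tsv")
        emit(de.shared_sbg_sets(bias), "sbg_sharing.tsv")
        emit(de.expression_variance_check(bias, norm, metadata),
             "variance_check.tsv")

    # ---- population genetics -------------------------------------------
    gene_stats = None
    if "popgen" in config.stages:
        vcf_data = io.read_vcf(data_dir / "genotypes.vcf")
        individuals = pd.read_csv(data_dir / "individuals.tsv", sep="\t")
        tables = []
        for sp in sorted(individuals["species"].unique()):
            sites = io.site_counts_for_species(vcf_data, individuals, sp)
            kept = popgen.apply_site_filters(sites)
            tab = popgen.gene_stats_table(kept, annotation)
            tab.insert(0, "species", sp)
            tables.append(tab)
        gene_stats = pd.concat(tables, ignore_index=True)
        emit(gene_stats, "popgen_stats.tsv")

    # ---- selection ------------------------------------------------------
    dnds = None
    deltax = None
    if "molevol" in config.stages:
        pairs = io.read_cds_pairs(data_dir / "cds_pairs.fasta")
        rows = []
        for gene in sorted(pairs):
            r = molevol.ng86_dnds(*pairs[gene])
            rows.append((gene, r.N, r.S_sites, r.Nd, r.Sd, r.dN, r.dS, r.omega))
        dnds = pd.DataFrame(rows, columns=["gene", "N", "S_sites", "Nd", "Sd",
                                           "dN", "dS", "omega"])
        emit(dnds, "dnds.tsv")
        lengths = (annotation.set_index("gene")["end"]
                   - annotation.set_index("gene")["start"] + 1)
        tpm = molevol.tpm_from_counts(counts, lengths)
        species = sorted(metadata["species"].unique())
        dx_tables = []
        for sp in species:
            ref = outgroup if sp != outgroup else _second_basal(tree, outgroup)
            dx_tables.append(molevol.delta_x_table(tpm, metadata, sp, ref))
        deltax = pd.concat(dx_tables, ignore_index=True)
        emit(deltax, "deltax.tsv")
        dnds_sp = dnds.assign(key=1).merge(
            pd.DataFrame({"species": species, "key": 1}), on="key").drop(columns="key")
        joint = molevol.joint_candidates(deltax, dnds_sp,
                                         dnds_cut=config.dnds_cut,
                                         deltax_cut=config.deltax_cut)
        joint = joint.merge(annotation[["gene", "lg"]], on="gene")
        emit(joint, "joint_candidates.tsv")

    # ---- expression phylogenies ----------------------------------------
    if "exprtree" in config.stages and bias is not None and norm is not None:
        _exprtree_stage(config, norm, metadata, bias, tree, annotation,
                        outgroup, emit)

    # ---- ancestral reconstruction + traits ------------------------------
    if "ancestral" in config.stages and bias is not None:
        _ancestral_stage(config, bias, tree, traits, emit)

    # ---- genomic distribution -------------------------------------------
    if "enrich" in config.stages and bias is not None:
        enr = genomedist.lg_enrichment(bias, annotation,
                                       organ=config.enrich_organ)
        emit(enr, "lg_enrichment.tsv")
        if gene_stats is not None:
            comp = _sexchr_stage(config, bias, gene_stats, dnds, annotation)
            emit(comp, "sexchr_vs_autosome.tsv")
        else:
            log.info("enrich: popgen stage disabled, "
                     "sex-chromosome Fst comparison skipped")

    manifest = {
        "config_hash": h,
        "seed": config.sim.seed,
        "stages": list(config.stages),
        "files": dict(sorted(written.items())),
        "outgroup": outgroup,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _second_basal(tree: dendropy.Tree, exclude: str) -> str:
    labels = sorted(t.taxon.label for t in tree.leaf_node_iter()
                    if t.taxon.label != exclude)
    depths = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == exclude:
            continue
        d, node = 0, leaf
        while node.parent_node is not None:
            d += 1
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return min(labels, key=depths.get)


def organ_profiles(norm: pd.DataFrame, metadata: pd.DataFrame,
                   organ: str) -> pd.DataFrame:
    """Mean normalized expression per species for one organ (sexes pooled)."""
    md = metadata.set_index("sample")
    cols = {}
    for sp, grp in md[md["organ"] == organ].groupby("species"):
        use = [s for s in grp.index if s in norm.columns]
        if use:
            cols[sp] = norm[use].mean(axis=1)
    return pd.DataFrame(cols)


def gene_classes(bias: pd.DataFrame, organ: str,
                 genes: pd.Index) -> pd.Series:
    """Per-gene class for one organ: MBG / FBG if biased in ≥1 species
    (MBG wins mixed cases by majority, ties MBG), else unbiased."""
    sub = bias[(bias["organ"] == organ) & bias["direction"].isin(["MBG", "FBG"])]
    votes = sub.groupby(["gene", "direction"]).size().unstack(fill_value=0)
    cls = pd.Series("unbiased", index=genes, name="bias_class")
    for g in votes.index.intersection(genes):
        m = votes.loc[g].get("MBG", 0)
        f = votes.loc[g].get("FBG", 0)
        cls[g] = "MBG" if m >= f else "FBG"
    return cls


def _exprtree_stage(config, norm, metadata, bias, species_tree, annotation,
                    outgroup, emit) -> None:
    organs = sorted(metadata["organ"].unique())
    rtt_rows, rf_rows, reg_rows, rate_rows = [], [], [], []
    newicks = []
    times = exprtree.divergence_times(species_tree)
    tmap = {(r.species_a, r.species_b): r.t for r in times.itertuples()}
    tmap.update({(b, a): t for (a, b), t in list(tmap.items())})
    for organ in organs:
        profiles = organ_profiles(norm, metadata, organ)
        if profiles.shape[1] < 4:
            continue
        classes = gene_classes(bias, organ, profiles.index)
        for cls in ("FBG", "MBG", "unbiased"):
            genes = classes[classes == cls].index
            if len(genes) < 3:
                continue
            prof = profiles.loc[genes]
            tree = exprtree.bootstrap_supports(prof, n_boot=config.n_boot,
                                               seed=config.sim.seed)
            newicks.append((organ, cls, tree.as_string(schema="newick").strip()))
            rooted = exprtree.root_tree(tree, outgroup=outgroup)
            for sp, v in exprtree.root_to_tip_lengths(rooted).items():
                rtt_rows.append((organ, cls, sp, v))
            pruned = species_tree.clone(depth=1)
            pruned.retain_taxa_with_labels(list(prof.columns))
            rf, rf_norm = exprtree.rf_distance(tree, pruned)
            rf_rows.append((organ, cls, rf, rf_norm))
            d = exprtree.spearman_distance_matrix(prof)
            for a, b in zip(*np.triu_indices(len(d), k=1)):
                sa, sb = d.columns[a], d.columns[b]
                t = tmap.get((sa, sb))
                if t:
                    rate_rows.append((organ, cls, sa, sb,
                                      exprtree.expression_rate(1 - d.iloc[a, b], t)))
        reg = exprtree.divergence_regression(profiles, species_tree)
        reg_rows.append((organ, reg["slope"], reg["intercept"], reg["r"],
                         reg["p"], len(reg["pairs"])))
    emit(pd.DataFrame(rtt_rows, columns=["organ", "bias_class", "species",
                                         "root_to_tip"]),
         "expr_root_to_tip.tsv")
    emit(pd.DataFrame(rf_rows, columns=["organ", "bias_class", "rf",
                                        "rf_normalized"]),
         "expr_rf.tsv")
    emit(pd.DataFrame(reg_rows, columns=["organ", "slope", "intercept", "r",
                                         "p", "n_pairs"]),
         "expr_divergence_regression.tsv")
    emit(pd.DataFrame(rate_rows, columns=["organ", "bias_class", "species_a",
                                          "species_b", "rate"]),
         "expr_rates.tsv")
    emit(pd.DataFrame(newicks, columns=["organ", "bias_class", "newick"]),
         "expr_trees.tsv")
    # per-LG correlations on the first organ with data
    for organ in organs:
        profiles = organ_profiles(norm, metadata, organ)
        if profiles.shape[1] < 3:
            continue
        lg_of = annotation.set_index("gene")["lg"]
        table, test = exprtree.per_lg_correlation(profiles, lg_of)
        table.insert(0, "organ", organ)
        emit(table, f"per_lg_rho_{organ}.tsv")
        break


def _ancestral_stage(config, bias, tree, traits, emit) -> None:
    organs = sorted(bias["organ"].unique())
    tips = sorted(t.taxon.label for t in tree.leaf_node_iter())
    fit_rows, turn_tables = [], []
    for organ in organs:
        sub = bias[bias["organ"] == organ]
        states = sub.pivot_table(index="gene", columns="species",
                                 values="direction", aggfunc="first")
        for sp in tips:
            if sp not in states.columns:
                states[sp] = np.nan
        states = states[tips].replace({"unbiased": "U"})
        informative = states.apply(
            lambda r: r.dropna().nunique() > 1 or "MBG" in set(r) or "FBG" in set(r),
            axis=1)
        states_f = states[informative]
        if states_f.empty:
            continue
        fit = ancestral.fit_mk_equal_rates(states_f, tree)
        fit_rows.append((organ, len(states_f), fit.q, fit.log_likelihood,
                         fit.boundary))
        nodes = ancestral.joint_ancestral_states(states_f, tree, fit)
        turns = ancestral.count_turnovers(states_f, nodes, tree)
        turns.insert(0, "organ", organ)
        turn_tables.append(turns)
    emit(pd.DataFrame(fit_rows, columns=["organ", "n_genes", "q",
                                         "log_likelihood", "boundary"]),
         "mk_fit.tsv")
    if not turn_tables:
        return
    turnovers = pd.concat(turn_tables, ignore_index=True)
    emit(turnovers, "branch_turnovers.tsv")
    term = turnovers[turnovers["terminal"]]
    totals = term.groupby("branch")[["gains_MBG", "losses_MBG", "gains_FBG",
                                     "losses_FBG"]].sum().sum(axis=1)
    pgls_rows = []
    for trait in traits.columns:
        try:
            fit = ancestral.pgls_trait_association(totals, traits[trait], tree)
        except ValueError as exc:
            log.info("ancestral: PGLS for %s skipped (%s)", trait, exc)
            continue
        pgls_rows.append((trait, fit["n"], fit["slope"], fit["se_slope"],
                          fit["t_slope"], fit["p_slope"]))
    emit(pd.DataFrame(pgls_rows, columns=["trait", "n", "slope", "se",
                                          "t", "p"]),
         "pgls_traits.tsv")


def _sexchr_stage(config, bias, gene_stats, dnds, annotation) -> pd.DataFrame:
    sexchr = {config.sim.xy_lg}
    tables = []
    for sp in sorted(gene_stats["species"].unique()):
        gs = gene_stats[gene_stats["species"] == sp].set_index("gene")
        cls = gene_classes(bias[bias["species"] == sp], config.enrich_organ,
                           gs.index)
        gs = gs.assign(bias_class=cls)
        stats_cols = ["fst", "pi", "tajimas_d"]
        if dnds is not None:
            gs = gs.join(dnds.set_index("gene")["omega"])
            stats_cols.append("omega")
        comp = genomedist.sexchr_vs_autosome_compare(gs, sexchr, stats_cols)
        comp.insert(0, "species", sp)
        tables.append(comp)
    return pd.concat(tables, ignore_index=True)
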