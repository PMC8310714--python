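"""Readers and writers for the pipeline's file dialects.

Counts, metadata, annotation, traits and result tables are TSV with a header
(comment lines starting with ``#`` ignored); annotation can also come from
GFF3 (1-based inclusive gene features with an ID attribute); genotypes from
VCF v4.2 with per-sample GT and DP; trees from newick with branch lengths.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_counts", "read_metadata", "read_annotation", "read_tree",
    "read_traits", "read_vcf", "site_counts_for_species", "read_cds_pairs",
    "write_table",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup}")
    if counts.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError(f"negative counts in {path}")
    return counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "species", "sex", "organ"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    if md["sample"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    bad = set(md["sex"]) - {"M", "F"}
    if bad:
        raise ValueError(f"sex labels must be M/F, got {sorted(bad)}")
    return md


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene → (lg, start, end), from a 4-column TSV or a GFF3 file."""
    path = Path(path)
    if path.suffix in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gene = attrs.get("ID")
                if gene is None:
                    raise ValueError(f"gene feature without ID in {path}: {line!r}")
                rows.append((gene, f[0], int(f[3]), int(f[4])))
        ann = pd.DataFrame(rows, columns=["gene", "lg", "start", "end"])
    else:
        ann = pd.read_csv(path, sep="\t", comment="#")
    if ann["gene"].duplicated().any():
        raise ValueError(f"duplicate genes in annotation {path}")
    if (ann["start"] < 1).any() or (ann["end"] < ann["start"]).any():
        raise ValueError(f"invalid 1-based gene intervals in {path}")
    return ann


def read_tree(path: str | Path, species: list[str] | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    if species is not None:
        tips = {t.taxon.label for t in tree.leaf_node_iter()}
        extra = tips - set(species)
        if extra:
            raise ValueError(f"tree tips absent from species set: {sorted(extra)}")
    return tree


def read_traits(path: str | Path) -> pd.DataFrame:
    tr = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if tr.index.duplicated().any():
        raise ValueError(f"duplicate species in traits {path}")
    return tr


def read_vcf(path: str | Path) -> dict:
    """Load per-site, per-sample genotypes and depth from a VCF.

    Returns arrays: ``lg``, ``pos``, ``qual`` per site; ``alleles`` of shape
    (sites, samples, 2) with −1 for missing calls; ``depth`` (sites,
    samples); and the sample name list. Biallelic SNP records only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    lg, pos, qual, geno, depth = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) > 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}")
        lg.append(v.CHROM)
        pos.append(v.POS)
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        g = np.array([gt[:2] for gt in v.genotypes], dtype=int)
        geno.append(g)
        dp = v.format("DP")
        depth.append(dp[:, 0] if dp is not None else np.zeros(len(samples), int))
    return {
        "lg": np.array(lg),
        "pos": np.array(pos, dtype=int),
        "qual": np.array(qual, dtype=float),
        "alleles": np.array(geno, dtype=int),
        "depth": np.array(depth, dtype=int),
        "samples": samples,
    }


def site_counts_for_species(vcf_data: dict, individuals: pd.DataFrame,
                            species: str) -> pd.DataFrame:
    """Per-site allele counts for one species, overall and by sex.

    ``individuals`` maps individual → species, sex; missing genotypes
    (either allele < 0 or depth 0) reduce the sampled copy numbers.
    """
    sub = individuals[individuals["species"] == species]
    idx = [vcf_data["samples"].index(i) for i in sub["individual"]]
    sex = sub["sex"].to_numpy()
    alle = vcf_data["alleles"][:, idx, :]
    depth = vcf_data["depth"][:, idx]
    called = (alle[:, :, 0] >= 0) & (alle[:, :, 1] >= 0) & (depth > 0)
    alt = np.where(called[:, :, None], alle, 0).sum(axis=2)
    male = sex == "M"
    female = ~male

    def group(mask):
        n = 2 * called[:, mask].sum(axis=1)
        d = np.where(called[:, mask], alt[:, mask], 0).sum(axis=1)
        return n, d

    n_all, d_all = group(np.ones(len(idx), bool))
    n_m, d_m = group(male)
    n_f, d_f = group(female)
    return pd.DataFrame({
        "lg": vcf_data["lg"],
        "pos": vcf_data["pos"],
        "qual": vcf_data["qual"],
        "n_covered": called.sum(axis=1),
        "n_covered_male": called[:, male].sum(axis=1),
        "n_covered_female": called[:, female].sum(axis=1),
        "total_depth": np.where(called, depth, 0).sum(axis=1),
        "n_all": n_all, "d_all": d_all,
        "n_male": n_m, "d_male": d_m,
        "n_female": n_f, "d_female": d_f,
    })


def read_cds_pairs(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the per-gene (reference, derived) aligned CDS pairs from FASTA
    with headers ``gene|ref`` and ``gene|derived``."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name, parts = line[1:], []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    pairs = {}
    for key, seq in seqs.items():
        gene, role = key.split("|", 1)
        pairs.setdefault(gene, {})[role] = seq
    out = {}
    for gene, d in pairs.items():
        if set(d) != {"ref", "derived"}:
            raise ValueError(f"gene {gene} lacks a ref/derived pair")
        out[gene] = (d["ref"], d["derived"])
    return out


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None,
                index: bool = False) -> None:
    """Write a result TSV, optionally with a config-hash comment header."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
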