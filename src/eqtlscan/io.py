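"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF v4.x (hard diploid calls); gene models, count
matrices, covariates and every result table are tab-separated text.
Coordinates are 1-based inclusive throughout, matching VCF — no
half-open conversion is ever exposed.

In-memory carriers:

* variant table  — DataFrame with columns snp_id ("CHR:POS"), chrom,
  pos, ref, alt, maf; one row per biallelic SNP.
* dosage matrix  — DataFrame, samples x variants, int8 ALT-allele
  counts in {0, 1, 2} with -1 for a missing call.
* gene table     — DataFrame with columns chrom, start, end, strand,
  gene_id, symbol, sorted by (chrom, start).
* count / expression matrices — DataFrame, genes x samples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import CoordinateError, FormatError, PloidyError

MISSING = -1  # dosage code for a missing genotype call

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "symbol"]
ASSOC_COLUMNS = [
    "snp_id", "gene_id", "beta", "se", "t", "p", "fdr",
    "class", "distance", "var_explained", "ci95_low", "ci95_high",
]
HOTSPOT_COLUMNS = ["snp_id", "class", "n_genes", "perm_p", "q", "shared_hub"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, split_multiallelic: bool = False):
    """Read hard diploid genotype calls from a VCF.

    Returns ``(variants, dosages)`` where dosages are ALT-allele counts
    per sample (0/1/2, ``MISSING`` for "./."). Multi-allelic records are
    rejected unless ``split_multiallelic`` is set, in which case each
    ALT allele becomes its own biallelic pseudo-record (dosage = count
    of that allele).
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, columns = [], []
    for var in vcf:
        alts = var.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and not split_multiallelic:
            raise FormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "pass split_multiallelic=True to split it"
            )
        calls = var.genotypes  # [a0, a1, phased] per sample
        for call in calls:
            if len(call) != 3:
                raise PloidyError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS}"
                )
        for ai, alt in enumerate(alts, start=1):
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for si, call in enumerate(calls):
                a0, a1 = call[0], call[1]
                if a0 < 0 or a1 < 0:
                    continue
                dos[si] = int(a0 == ai) + int(a1 == ai)
            suffix = "" if len(alts) == 1 else f"_{alt}"
            snp_id = f"{var.CHROM}:{var.POS}{suffix}"
            rows.append((snp_id, var.CHROM, var.POS, var.REF, alt))
            columns.append(dos)
    variants = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    )
    if variants["snp_id"].duplicated().any():
        dupes = variants.loc[variants["snp_id"].duplicated(), "snp_id"]
        raise FormatError(f"duplicate variant records: {sorted(set(dupes))}")
    dosages = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0), np.int8),
        index=pd.Index(samples, name="sample_id"),
        columns=variants["snp_id"].tolist(),
        dtype=np.int8,
    )
    from .preprocess import compute_maf  # deferred; avoids import cycle

    variants["maf"] = [
        compute_maf(dosages[s].to_numpy()) if (dosages[s] != MISSING).any() else 0.0
        for s in variants["snp_id"]
    ]
    return variants, dosages


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path: str | Path, variants: pd.DataFrame, dosages: pd.DataFrame) -> None:
    """Write biallelic hard calls as a minimal VCF v4.2 with GT only."""
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort")
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in samples)
            + "\n"
        )
        for row in variants.itertuples(index=False):
            gts = "\t".join(
                _GT_STRINGS[int(d)] for d in dosages[row.snp_id].to_numpy()
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV of gene models (1-based inclusive coordinates).

    Columns: chrom, start, end, strand, gene_id, symbol. Output is
    sorted by (chrom, start); duplicate gene ids are rejected.
    """
    genes = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise FormatError(f"gene-model file lacks columns: {sorted(missing)}")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "gene_id"].tolist()
        raise CoordinateError(f"start >= end for genes: {bad}")
    if (genes["start"] < 1).any():
        raise CoordinateError("gene start coordinates must be >= 1 (1-based)")
    bad_strand = ~genes["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"unknown strand symbols: {sorted(set(genes.loc[bad_strand, 'strand']))}"
        )
    if genes["gene_id"].duplicated().any():
        dupes = genes.loc[genes["gene_id"].duplicated(), "gene_id"]
        raise FormatError(f"duplicated gene ids: {sorted(set(dupes))}")
    return (
        genes[GENE_COLUMNS]
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_gene_models(path: str | Path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        genes[GENE_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path: str | Path, matrix: pd.DataFrame, index_name: str = "gene_id") -> None:
    matrix = matrix.copy()
    matrix.index.name = index_name
    matrix.to_csv(path, sep="\t")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate table (sample_id, age in months)."""
    cov = pd.read_csv(path, sep="\t")
    if "sample_id" not in cov.columns or "age" not in cov.columns:
        raise FormatError("covariate file needs columns: sample_id, age")
    if cov["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in covariate file")
    if (cov["age"] <= 0).any():
        raise FormatError("ages must be positive")
    return cov.set_index("sample_id")


def write_covariates(path: str | Path, covariates: pd.DataFrame) -> None:
    out = covariates.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV result table (associations, hotspots, truth...)."""
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
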