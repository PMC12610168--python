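"""Stage orchestration: chain preprocess -> scan -> hotspots -> enrich
over a working directory of TSV/VCF files.

Each stage reads the previous stage's outputs from the directory and
writes its own, so the CLI subcommands and the `all` chain share one
code path. File names are fixed:

    genotypes.vcf, genes.tsv, counts.tsv, covariates.tsv   (inputs)
    variants_qc.tsv, dosages_qc.tsv, expression.tsv, qc_report.tsv
    cis_eqtls.tsv, trans_eqtls.tsv, top_cis_pairs.tsv, qq_cis.tsv,
    qq_trans.tsv, scan_counts.tsv
    hotspots.tsv, perm_counts.tsv
    enrichment.tsv
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .errors import PipelineError
from . import preprocess as pp
from . import hotspots as hs
from . import enrich as en
from .association import qq_data, scan as run_assoc_scan, top_per_gene

log = logging.getLogger(__name__)


def _need(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def run_preprocess(workdir: str | Path, config: PipelineConfig) -> dict:
    """Genotype QC (MAF > maf_min, LD pruning, near-gene restriction)
    and expression filtering + normalization."""
    wd = Path(workdir)
    variants, dosages = eio.read_vcf(_need(wd / "genotypes.vcf"))
    genes = eio.read_gene_models(_need(wd / "genes.tsv"))
    counts = eio.read_matrix(_need(wd / "counts.tsv"))

    report = [("variants_input", len(variants)), ("genes_input", len(counts))]
    variants, dosages = pp.filter_variants(variants, dosages, config.maf_min)
    report.append(("variants_maf_filtered", len(variants)))
    kept = pp.ld_prune(
        variants, dosages, config.ld_window_snps, config.ld_step_snps, config.ld_r2_max
    )
    variants = variants[variants["snp_id"].isin(kept)].reset_index(drop=True)
    report.append(("variants_ld_pruned", len(variants)))

    counts = pp.filter_genes(counts, config.min_gene_total, config.zero_sample_limit)
    report.append(("genes_expressed", len(counts)))
    genes_kept = genes[genes["gene_id"].isin(counts.index)].reset_index(drop=True)
    expression = pp.normalize(counts)
    # keep expression rows in gene-model order
    expression = expression.loc[genes_kept["gene_id"]]

    variants = pp.restrict_near_genes(variants, genes_kept, config.cis_window)
    report.append(("variants_near_genes", len(variants)))
    dosages = dosages[variants["snp_id"].tolist()]

    eio.write_table(wd / "variants_qc.tsv", variants)
    eio.write_matrix(wd / "dosages_qc.tsv", dosages.T, index_name="snp_id")
    eio.write_matrix(wd / "expression.tsv", expression)
    eio.write_table(wd / "qc_report.tsv", pd.DataFrame(report, columns=["stage", "count"]))
    for stage, count in report:
        log.info("preprocess %s: %d", stage, count)
    return {"variants": variants, "dosages": dosages, "expression": expression,
            "genes": genes_kept}


def _load_stage_inputs(wd: Path):
    variants = eio.read_table(_need(wd / "variants_qc.tsv"))
    dosages = eio.read_matrix(_need(wd / "dosages_qc.tsv")).T.astype("int8")
    dosages.index.name = "sample_id"
    expression = eio.read_matrix(_need(wd / "expression.tsv"))
    genes = eio.read_gene_models(_need(wd / "genes.tsv"))
    genes = genes[genes["gene_id"].isin(expression.index)].reset_index(drop=True)
    covariates = eio.read_covariates(_need(wd / "covariates.tsv"))
    return variants, dosages, expression, genes, covariates


def run_scan(workdir: str | Path, config: PipelineConfig) -> dict:
    """Association scan + per-gene reduction + QQ tables."""
    wd = Path(workdir)
    variants, dosages, expression, genes, covariates = _load_stage_inputs(wd)
    cis, trans, counts = run_assoc_scan(expression, dosages, covariates, genes, variants, config)
    top = top_per_gene(cis, config.fdr_max)
    eio.write_table(wd / "cis_eqtls.tsv", cis)
    eio.write_table(wd / "trans_eqtls.tsv", trans)
    eio.write_table(wd / "top_cis_pairs.tsv", top)
    if len(cis):
        eio.write_table(wd / "qq_cis.tsv", qq_data(cis["p"]))
    if len(trans):
        eio.write_table(wd / "qq_trans.tsv", qq_data(trans["p"]))
    eio.write_table(
        wd / "scan_counts.tsv",
        pd.DataFrame(list(counts.items()), columns=["quantity", "count"]),
    )
    return {"cis": cis, "trans": trans, "top": top, "counts": counts}


def run_hotspots(workdir: str | Path, config: PipelineConfig, B: int | None = None,
                 seed: int | None = None) -> dict:
    """Hotspot discovery + permutation FDR + shared-hub flagging."""
    wd = Path(workdir)
    variants, dosages, expression, genes, covariates = _load_stage_inputs(wd)
    cis = eio.read_table(_need(wd / "cis_eqtls.tsv"))
    trans = eio.read_table(_need(wd / "trans_eqtls.tsv"))
    B = B if B is not None else config.n_permutations

    cis_counts = hs.count_regulated_genes(cis, "cis", config.fdr_max)
    cis_hot = hs.cis_hotspots(cis_counts, config.cis_hotspot_min_genes)
    trans_counts = hs.count_regulated_genes(trans, "trans", config.fdr_max)
    if len(trans_counts):
        trans_hot = hs.trans_hotspots(trans_counts, config.trans_hotspot_percentile)
    else:
        trans_hot = pd.DataFrame(columns=["snp_id", "class", "n_genes"])

    if len(trans_hot):
        perm, perm_counts = hs.permutation_test(
            expression, dosages, covariates, genes, variants,
            trans_hot["snp_id"].tolist(), B, config, seed=seed,
        )
        q, sig = hs.hotspot_fdr(perm["perm_p"].to_numpy(), config.fdr_max)
        trans_hot = trans_hot.merge(perm[["snp_id", "perm_p"]], on="snp_id")
        trans_hot["q"] = q
        trans_hot = hs.flag_shared_hubs(trans_hot, cis, config.fdr_max)
        eio.write_table(wd / "perm_counts.tsv", perm_counts)
    else:
        trans_hot = trans_hot.assign(perm_p=pd.NA, q=pd.NA, shared_hub=pd.NA)

    cis_hot = cis_hot.assign(perm_p=pd.NA, q=pd.NA, shared_hub=pd.NA)
    frames = [f[eio.HOTSPOT_COLUMNS] for f in (cis_hot, trans_hot) if len(f)]
    if frames:
        hot = pd.concat(frames, ignore_index=True)
    else:
        hot = pd.DataFrame(columns=eio.HOTSPOT_COLUMNS)
    eio.write_table(wd / "hotspots.tsv", hot)
    return {"hotspots": hot, "cis_counts": cis_counts, "trans_counts": trans_counts}


def run_enrich(workdir: str | Path, config: PipelineConfig,
               gmt_path: str | Path | None = None) -> dict:
    """Enrichment of the top cis eGene set against a GMT term collection.

    Background = all genes surviving the expression filter.
    """
    wd = Path(workdir)
    gmt_path = Path(gmt_path) if gmt_path else wd / "terms.gmt"
    terms = en.read_gmt(_need(gmt_path))
    expression = eio.read_matrix(_need(wd / "expression.tsv"))
    top = eio.read_table(_need(wd / "top_cis_pairs.tsv"))
    background = list(expression.index)
    query = [g for g in top["gene_id"].unique() if g in set(background)]
    if not query:
        raise PipelineError("no significant eGenes to enrich")
    records = en.hypergeom_enrich(query, terms, background)
    records = en.cluster_terms(records, terms, background, config.kappa_min)
    eio.write_table(wd / "enrichment.tsv", records)
    return {"enrichment": records}


def run_all(workdir: str | Path, config: PipelineConfig, B: int | None = None,
            seed: int | None = None, gmt_path: str | Path | None = None) -> dict:
    """Chain preprocess -> scan -> hotspots (-> enrich if a GMT exists)."""
    wd = Path(workdir)
    out = {}
    out.update(run_preprocess(wd, config))
    out.update(run_scan(wd, config))
    out.update(run_hotspots(wd, config, B=B, seed=seed))
    gmt = Path(gmt_path) if gmt_path else wd / "terms.gmt"
    if gmt.exists() and len(out["top"]):
        out.update(run_enrich(wd, config, gmt))
    return out
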