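"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes for a
75-animal bulk RNA-seq + genotyping study: Hardy-Weinberg genotypes
with configurable MAF range and optional LD blocks, non-overlapping
gene models, planted additive cis effects within ±100 kb of genes,
planted trans master-regulator SNPs affecting tens of distant genes
(optionally sharing a hub SNP with a cis effect), an age covariate
emulating a fattening-steer cohort (mean 14.3, SD 8.8 months,
truncated at 1 month), and a negative-binomial count layer
over a latent Gaussian expression layer.

The planted-effect ledger (truth table) records every effect with its
SNP, gene, mode (additive or heterozygote-peak) and beta in latent-SD
units per allele copy, enabling recovery-based tests downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import CapacityError, PipelineError, PlantingError
from . import io as eio
from .preprocess import distance_to_interval

AGE_MEAN_MONTHS = 14.3
AGE_SD_MONTHS = 8.8

TRUTH_COLUMNS = ["snp_id", "gene_id", "mode", "beta", "class"]


def _child_rng(seed, *salt) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


# ---------------------------------------------------------------------------
# Genome scaffold
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    n_snps: int,
    seed: int = 0,
    gene_len_range: tuple[int, int] = (2_000, 20_000),
    guarantee_cis_snp: bool = True,
    cis_window: int = 100_000,
):
    """Lay out non-overlapping genes and SNP positions.

    Genes are distributed round-robin over chromosomes and packed with
    random gaps; SNP positions are uniform, except that with
    ``guarantee_cis_snp`` one SNP is placed inside each gene so every
    gene has at least one cis-testable variant.

    Returns ``(genes, variants)`` tables per :mod:`eqtlscan.io`.
    """
    rng = _child_rng(seed, 1)
    chroms = [str(c + 1) for c in range(n_chrom)]
    per_chrom = [n_genes // n_chrom + (c < n_genes % n_chrom) for c in range(n_chrom)]
    max_len = gene_len_range[1]
    for k in per_chrom:
        if k * max_len >= chrom_len:
            raise CapacityError(
                f"{k} genes of up to {max_len} bp cannot fit a "
                f"{chrom_len} bp chromosome"
            )
    gene_rows = []
    gi = 0
    for chrom, k in zip(chroms, per_chrom):
        lengths = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=k)
        free = chrom_len - int(lengths.sum())
        # gaps between/around genes: random split of the free space
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts]))
        start = 1
        for j in range(k):
            start = start + int(gaps[j])
            end = start + int(lengths[j]) - 1
            gi += 1
            gene_rows.append((chrom, start, end, "+" if rng.random() < 0.5 else "-",
                              f"G{gi:05d}", f"GENE{gi}"))
            start = end + 1
    genes = pd.DataFrame(gene_rows, columns=eio.GENE_COLUMNS)

    snp_rows = []
    seen: set[tuple[str, int]] = set()
    if guarantee_cis_snp:
        for g in genes.itertuples(index=False):
            pos = int(rng.integers(g.start, g.end + 1))
            while (g.chrom, pos) in seen:
                pos = int(rng.integers(g.start, g.end + 1))
            seen.add((g.chrom, pos))
            snp_rows.append((g.chrom, pos))
    if len(snp_rows) > n_snps:
        raise CapacityError(
            f"n_snps={n_snps} is fewer than the {len(snp_rows)} guaranteed cis SNPs"
        )
    while len(snp_rows) < n_snps:
        chrom = chroms[int(rng.integers(0, n_chrom))]
        pos = int(rng.integers(1, chrom_len + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        snp_rows.append((chrom, pos))
    alleles = ["A", "C", "G", "T"]
    variants = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ref_i = rng.integers(0, 4, size=len(variants))
    alt_i = (ref_i + rng.integers(1, 4, size=len(variants))) % 4
    variants["snp_id"] = variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
    variants["ref"] = [alleles[i] for i in ref_i]
    variants["alt"] = [alleles[i] for i in alt_i]
    variants["maf"] = np.nan
    variants = variants[["snp_id", "chrom", "pos", "ref", "alt", "maf"]]
    return genes, variants


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    variants: pd.DataFrame,
    n_samples: int,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    ld_block: int = 1,
    flip_noise: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Hardy-Weinberg dosages with optional block LD structure.

    Consecutive SNPs on a chromosome are grouped into blocks of
    ``ld_block``; the block founder draws its allele frequency uniform
    in [maf_low, maf_high] and its genotypes under HWE, and every other
    block member copies the founder, each sample independently redrawn
    from HWE with probability ``flip_noise``. ``ld_block=1`` gives
    independent SNPs; zero flip noise gives within-block r^2 = 1.
    Columns that come out monomorphic in the sample are redrawn (a
    zero-variance dosage vector cannot be association-tested).
    """
    if n_samples < 2:
        raise PipelineError("need at least 2 samples")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise PipelineError("require 0 < maf_low <= maf_high <= 0.5")
    rng = _child_rng(seed, 2)
    cols = {}
    for _, chrom_vars in variants.groupby("chrom", sort=False):
        ids = chrom_vars.sort_values("pos")["snp_id"].tolist()
        for b0 in range(0, len(ids), ld_block):
            block = ids[b0:b0 + ld_block]
            f = rng.uniform(maf_low, maf_high)
            founder = rng.binomial(2, f, size=n_samples)
            for attempt in range(100):
                if founder.std() > 0:
                    break
                founder = rng.binomial(2, f, size=n_samples)
            for k, snp in enumerate(block):
                if k == 0:
                    cols[snp] = founder.astype(np.int8)
                    continue
                g = founder.copy()
                flip = rng.random(n_samples) < flip_noise
                g[flip] = rng.binomial(2, f, size=int(flip.sum()))
                for attempt in range(100):
                    if g.std() > 0:
                        break
                    g = founder.copy()
                    flip = rng.random(n_samples) < max(flip_noise, 0.05)
                    g[flip] = rng.binomial(2, f, size=int(flip.sum()))
                cols[snp] = g.astype(np.int8)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(
        {s: cols[s] for s in variants["snp_id"]},
        index=pd.Index(samples, name="sample_id"),
        dtype=np.int8,
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    n_samples: int,
    age_mean: float = AGE_MEAN_MONTHS,
    age_sd: float = AGE_SD_MONTHS,
    seed: int = 0,
) -> pd.DataFrame:
    """Ages in months, normal truncated at 1 month (redraw below)."""
    rng = _child_rng(seed, 3)
    ages = np.empty(n_samples)
    for i in range(n_samples):
        a = rng.normal(age_mean, age_sd)
        while a < 1.0:
            a = rng.normal(age_mean, age_sd)
        ages[i] = a
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame({"age": np.round(ages, 2)}, index=pd.Index(samples, name="sample_id"))


# ---------------------------------------------------------------------------
# Planted effects
# ---------------------------------------------------------------------------

def plant_effects(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    cis_fraction: float = 0.2,
    cis_beta: float = 1.5,
    hotspot_spec: list[tuple[int, float]] | None = None,
    mode: str = "additive",
    shared_hub: bool = False,
    cis_window: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Choose SNP-gene pairs and effect sizes; return the truth ledger.

    A fraction ``cis_fraction`` of genes receives a cis effect from a
    SNP within ``cis_window`` of the gene body, with |beta| =
    ``cis_beta`` latent-SD units per allele copy and random sign. Each
    entry of ``hotspot_spec`` = (n_targets, beta) plants one trans
    master-regulator SNP whose targets are sampled from genes beyond
    the window or on other chromosomes. With ``shared_hub`` the first
    hotspot SNP is chosen so that it also carries a cis effect on a
    nearby gene, emulating a locus where cis and trans regulation
    converge. ``mode`` ('additive' or 'het_peak') applies to the cis
    effects; trans effects are always additive.
    """
    if not (0.0 <= cis_fraction <= 1.0):
        raise PipelineError("cis_fraction must be in [0, 1]")
    if mode not in ("additive", "het_peak"):
        raise PipelineError(f"unknown effect mode: {mode}")
    rng = _child_rng(seed, 4)
    hotspot_spec = hotspot_spec or []
    records = []

    # candidate cis SNPs per gene
    by_chrom = {c: v.sort_values("pos") for c, v in variants.groupby(variants["chrom"].astype(str))}

    def cis_snps_of(g) -> list[str]:
        sub = by_chrom.get(str(g.chrom))
        if sub is None:
            return []
        d = np.maximum(0, np.maximum(g.start - sub["pos"].to_numpy(), sub["pos"].to_numpy() - g.end))
        return sub.loc[d <= cis_window, "snp_id"].tolist()

    n_cis = int(round(cis_fraction * len(genes)))
    order = rng.permutation(len(genes))
    chosen = []
    for idx in order:
        if len(chosen) == n_cis:
            break
        g = genes.iloc[idx]
        cands = cis_snps_of(g)
        if not cands:
            continue
        snp = cands[int(rng.integers(0, len(cands)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        records.append((snp, g.gene_id, mode, sign * cis_beta, "cis"))
        chosen.append(g.gene_id)
    if len(chosen) < n_cis:
        raise PlantingError(
            f"only {len(chosen)} of {n_cis} requested cis effects could be "
            "planted: some genes have no SNP within the cis window"
        )

    gene_pos = genes.set_index("gene_id")
    for hi, (n_targets, beta) in enumerate(hotspot_spec):
        if shared_hub and hi == 0:
            # pick a SNP inside/near a gene and give it a cis effect too
            hub_snp = None
            for idx in rng.permutation(len(genes)):
                g = genes.iloc[idx]
                cands = cis_snps_of(g)
                if cands:
                    hub_snp = cands[int(rng.integers(0, len(cands)))]
                    records.append((hub_snp, g.gene_id, mode, cis_beta, "cis"))
                    break
            if hub_snp is None:
                raise PlantingError("no SNP near any gene for the shared hub")
        else:
            hub_snp = variants["snp_id"].iloc[int(rng.integers(0, len(variants)))]
        vrow = variants.set_index("snp_id").loc[hub_snp]
        eligible = []
        for g in genes.itertuples(index=False):
            if str(g.chrom) != str(vrow["chrom"]):
                eligible.append(g.gene_id)
            elif distance_to_interval(int(vrow["pos"]), g.start, g.end) > cis_window:
                eligible.append(g.gene_id)
        if len(eligible) < n_targets:
            raise PlantingError(
                f"hotspot {hub_snp} has only {len(eligible)} eligible distant "
                f"genes, {n_targets} requested"
            )
        targets = rng.choice(eligible, size=n_targets, replace=False)
        for gid in targets:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            records.append((hub_snp, gid, "additive", sign * beta, "trans"))

    return pd.DataFrame(records, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    dosages: pd.DataFrame,
    truth: pd.DataFrame,
    covariates: pd.DataFrame,
    gene_ids,
    age_beta: float = 0.0,
    noise_sd: float = 1.0,
    nb_dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (5e5, 1.5e6),
    baseline_sd: float = 1.0,
    seed: int = 0,
):
    """Latent Gaussian expression plus a negative-binomial count layer.

    latent[g, s] = baseline_g + sum of planted effects(dosage)
                   + age_beta * age_s + N(0, noise_sd^2)

    An additive effect contributes beta * dosage; a het_peak effect
    contributes beta * 1[dosage == 1] (highest in heterozygotes).
    Counts are negative-binomial with per-sample mean
    lib_size_s * softmax_g(latent[:, s]) and dispersion
    ``nb_dispersion`` (variance mu + dispersion * mu^2). Genes absent
    from the truth table are pure noise.

    Returns ``(latent, counts)`` as genes x samples DataFrames.
    """
    if noise_sd <= 0 or nb_dispersion <= 0:
        raise PipelineError("noise_sd and nb_dispersion must be positive")
    gene_ids = list(gene_ids)
    samples = list(dosages.index)
    if set(samples) != set(covariates.index):
        raise PipelineError("dosage and covariate sample sets differ")
    rng = _child_rng(seed, 5)
    n_g, n_s = len(gene_ids), len(samples)
    baseline = rng.normal(0.0, baseline_sd, size=n_g)
    latent = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_g, n_s))
    ages = covariates.loc[samples, "age"].to_numpy(float)
    latent += age_beta * ages[None, :]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for rec in truth.itertuples(index=False):
        if rec.gene_id not in gidx:
            raise PipelineError(f"truth gene {rec.gene_id} not in gene_ids")
        d = dosages[rec.snp_id].to_numpy(float)
        if rec.mode == "additive":
            latent[gidx[rec.gene_id]] += rec.beta * d
        elif rec.mode == "het_peak":
            latent[gidx[rec.gene_id]] += rec.beta * (d == 1)
        else:
            raise PipelineError(f"unknown effect mode {rec.mode}")
    latent_df = pd.DataFrame(latent, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    lib = rng.uniform(*lib_size_range, size=n_s)
    w = np.exp(latent - latent.max(axis=0, keepdims=True))
    mu = lib[None, :] * w / w.sum(axis=0, keepdims=True)
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, mu * nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return latent_df, counts_df


# ---------------------------------------------------------------------------
# End-to-end study generator
# ---------------------------------------------------------------------------

def simulate_study(
    outdir: str | Path,
    n_samples: int = 75,
    n_chrom: int = 4,
    chrom_len: int = 12_000_000,
    n_genes: int = 400,
    n_snps: int = 1_500,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    ld_block: int = 3,
    flip_noise: float = 0.1,
    cis_fraction: float = 0.15,
    cis_beta: float = 1.5,
    hotspot_spec: list[tuple[int, float]] | None = ((40, 1.5), (15, 1.5)),
    shared_hub: bool = True,
    age_beta: float = 0.0,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Generate and write a complete synthetic study to ``outdir``.

    Defaults emulate a realistic cohort at desk scale: 75 samples, a
    multi-chromosome genome with ~400 expressed genes, planted cis
    effects, a large and a medium trans hub (the large one shared with
    a cis signal). Writes genotypes.vcf, genes.tsv, counts.tsv,
    covariates.tsv and truth.tsv; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    genes, variants = simulate_genome(
        n_chrom, chrom_len, n_genes, n_snps, seed=seed, cis_window=config.cis_window
    )
    dosages = simulate_genotypes(
        variants, n_samples, maf_low, maf_high, ld_block, flip_noise, seed=seed
    )
    covariates = simulate_covariates(n_samples, seed=seed)
    truth = plant_effects(
        genes, variants, cis_fraction, cis_beta,
        list(hotspot_spec) if hotspot_spec else [],
        shared_hub=shared_hub, cis_window=config.cis_window, seed=seed,
    )
    _, counts = simulate_expression(
        dosages, truth, covariates, genes["gene_id"], age_beta=age_beta, seed=seed
    )
    from .preprocess import compute_maf

    variants = variants.copy()
    variants["maf"] = [compute_maf(dosages[s].to_numpy()) for s in variants["snp_id"]]
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "genes": outdir / "genes.tsv",
        "counts": outdir / "counts.tsv",
        "covariates": outdir / "covariates.tsv",
        "truth": outdir / "truth.tsv",
    }
    eio.write_vcf(paths["vcf"], variants, dosages)
    eio.write_gene_models(paths["genes"], genes)
    eio.write_matrix(paths["counts"], counts)
    eio.write_covariates(paths["covariates"], covariates)
    eio.write_table(paths["truth"], truth)
    return paths
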