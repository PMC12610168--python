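"""Genotype and expression quality control.

Genotype side: minor-allele-frequency filtering (keep strictly
MAF > 0.01), PLINK-style ``indep-pairwise`` LD pruning (drop one SNP of
any within-window pair with r^2 >= 0.2), and restriction to SNPs within
or near expressed genes. Order of operations: MAF filter, then LD
pruning, then the near-gene restriction.

Expression side: removal of lowly expressed genes (total count < 200
or zero counts in >= 70 of 75 samples, rescaled for other cohort
sizes) and a variance-stabilizing normalization stand-in —
median-of-ratios size factors followed by log2(count / sf + 1). The
stand-in keeps the two properties the association scan relies on,
approximate variance stabilization and library-size invariance.

A positional variant-context labeler provides coarse annotation
(genic / exonic / intronic / upstream / downstream / intergenic).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigError, PipelineError, SizeFactorError
from .io import MISSING

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def compute_maf(dosage_vector: np.ndarray) -> float:
    """Minor allele frequency of a dosage vector (0/1/2, -1 = missing).

    f = sum(dosage) / (2 * n_nonmissing); returns min(f, 1 - f).
    """
    d = np.asarray(dosage_vector)
    ok = d != MISSING
    n = int(ok.sum())
    if n == 0:
        raise PipelineError("MAF undefined: all genotype calls missing")
    f = float(d[ok].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def filter_variants(
    variants: pd.DataFrame, dosages: pd.DataFrame, maf_min: float = 0.01
):
    """Keep variants with MAF strictly greater than ``maf_min``.

    Monomorphic SNPs (MAF 0) are always dropped. MAFs are recomputed
    from the dosage matrix so that the filter and the stored ``maf``
    column cannot disagree.
    """
    mafs = np.array(
        [compute_maf(dosages[s].to_numpy()) for s in variants["snp_id"]]
    )
    keep = mafs > maf_min
    out = variants.loc[keep].copy()
    out["maf"] = mafs[keep]
    out = out.reset_index(drop=True)
    return out, dosages[out["snp_id"].tolist()]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on the 0/1/2 codes (the PLINK definition), pairwise
    complete over missing calls. Returns 0 when either vector is
    constant on the shared samples.
    """
    ok = (a != MISSING) & (b != MISSING)
    x, y = a[ok].astype(float), b[ok].astype(float)
    if len(x) < 2:
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _chrom_r2_lookup(G: np.ndarray):
    """Pairwise r^2 lookup for one chromosome's snps x samples block.

    Precomputes the full correlation matrix when there are no missing
    calls (cheap at pipeline scale); falls back to pairwise-complete
    per-pair computation otherwise.
    """
    if not (G == MISSING).any():
        Gc = G.astype(float) - G.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", Gc, Gc))
        with np.errstate(divide="ignore", invalid="ignore"):
            C = (Gc @ Gc.T) / np.outer(norms, norms)
        R2 = np.nan_to_num(C * C)
        return lambda i, j: float(R2[i, j])
    return lambda i, j: dosage_r2(G[i], G[j])


def ld_prune(
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """PLINK-style ``indep-pairwise`` pruning; returns retained snp_ids.

    Per chromosome, in position order: within each sliding window of
    ``window_snps`` retained SNPs every pair with r^2 >= ``r2_max``
    loses its later-positioned member, and the window advances by
    ``step_snps``. Passes repeat (the last with single-SNP stride)
    until stable, so on return NO retained pair within ``window_snps``
    consecutive retained SNPs reaches ``r2_max``.
    """
    if window_snps < 2:
        raise ConfigError("ld_prune window must span at least 2 SNPs")
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort")
    retained: list[str] = []
    for _, chrom_vars in variants.groupby("chrom", sort=False):
        ids = chrom_vars["snp_id"].tolist()
        G = dosages[ids].to_numpy().T  # snps x samples
        r2 = _chrom_r2_lookup(G)
        alive = np.ones(len(ids), dtype=bool)

        def _pass(stride: int) -> bool:
            removed = False
            alive_idx = np.where(alive)[0]
            for a0 in range(0, max(1, len(alive_idx) - 1), stride):
                win = [i for i in alive_idx[a0:a0 + window_snps] if alive[i]]
                for wi, i in enumerate(win):
                    if not alive[i]:
                        continue
                    for j in win[wi + 1:]:
                        if alive[j] and r2(i, j) >= r2_max:
                            alive[j] = False  # drop the later-positioned SNP
                            removed = True
            return removed

        while _pass(step_snps):
            pass
        while _pass(1):  # cleanup: enforce the window-wide postcondition
            pass
        retained.extend(np.array(ids)[alive].tolist())
    return retained


# ---------------------------------------------------------------------------
# Near-gene restriction
# ---------------------------------------------------------------------------

def distance_to_interval(pos: int, start: int, end: int) -> int:
    """bp distance of a position to a 1-based inclusive interval (0 inside)."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def restrict_near_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, window: int = 100_000
) -> pd.DataFrame:
    """Keep SNPs within ``window`` bp (inclusive) of any retained gene."""
    if len(genes) == 0:
        log.warning("restrict_near_genes: empty gene set; all SNPs dropped")
        return variants.iloc[0:0].copy()
    keep = np.zeros(len(variants), dtype=bool)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        vmask = (variants["chrom"].astype(str) == str(chrom)).to_numpy()
        if not vmask.any():
            continue
        pos = variants.loc[vmask, "pos"].to_numpy()[:, None]
        starts = gsub["start"].to_numpy()[None, :]
        ends = gsub["end"].to_numpy()[None, :]
        dist = np.maximum(0, np.maximum(starts - pos, pos - ends))
        keep[vmask] = dist.min(axis=1) <= window
    return variants.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression filtering and normalization
# ---------------------------------------------------------------------------

def filter_genes(
    counts: pd.DataFrame,
    min_total: int = 200,
    zero_sample_limit: int | None = None,
) -> pd.DataFrame:
    """Drop lowly expressed genes.

    A gene is removed when its total count is below ``min_total`` OR it
    has zero counts in at least ``zero_sample_limit`` samples. With the
    limit unset it defaults to ceil(70/75 * n_samples), the 70-of-75
    rule rescaled to the cohort at hand.
    """
    n = counts.shape[1]
    if zero_sample_limit is None:
        zero_sample_limit = math.ceil(70 / 75 * n)
    totals = counts.sum(axis=1)
    zeros = (counts == 0).sum(axis=1)
    keep = (totals >= min_total) & (zeros < zero_sample_limit)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: median over all-positive genes of count / geometric
    mean of that gene across samples. Genes with any zero count are
    excluded from the median.
    """
    allpos = counts.loc[(counts > 0).all(axis=1)]
    if allpos.empty:
        raise SizeFactorError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — filter samples or supply deeper counts"
        )
    logc = np.log(allpos.to_numpy(dtype=float))
    log_gmean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_gmean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing normalization stand-in.

    log2(count / size_factor + 1) with median-of-ratios size factors.
    Scaling all of one sample's counts by c scales its size factor by c
    and leaves the normalized values invariant (exactly so up to the
    +1 offset, which is second order at realistic counts).
    """
    if counts.shape[1] < 2:
        raise PipelineError("normalization needs at least 2 samples")
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


# ---------------------------------------------------------------------------
# Positional variant context
# ---------------------------------------------------------------------------

def classify_variant_context(
    chrom: str,
    pos: int,
    genes: pd.DataFrame,
    upstream_bp: int = 5000,
    downstream_bp: int = 5000,
    exons: pd.DataFrame | None = None,
) -> str:
    """Coarse positional label for one variant.

    Labels: ``genic_exonic`` / ``genic_intronic`` when exon
    sub-intervals are supplied (columns gene_id, start, end), plain
    ``genic`` otherwise; strand-aware ``upstream`` / ``downstream``
    within the given flanks; else ``intergenic``. When several genes
    qualify the nearest wins, genic context beating flanking context.
    """
    gsub = genes[genes["chrom"].astype(str) == str(chrom)]
    best_label, best_dist = "intergenic", None
    for g in gsub.itertuples(index=False):
        if g.start <= pos <= g.end:
            if exons is not None:
                ex = exons[exons["gene_id"] == g.gene_id]
                in_exon = ((ex["start"] <= pos) & (pos <= ex["end"])).any()
                return "genic_exonic" if in_exon else "genic_intronic"
            return "genic"
        if pos < g.start:
            dist, side = g.start - pos, "before"
        else:
            dist, side = pos - g.end, "after"
        # 5' flank is upstream on + strand; orientation flips on -
        if g.strand == "+":
            label, limit = (
                ("upstream", upstream_bp) if side == "before" else ("downstream", downstream_bp)
            )
        else:
            label, limit = (
                ("downstream", downstream_bp) if side == "before" else ("upstream", upstream_bp)
            )
        if dist <= limit and (best_dist is None or dist < best_dist):
            best_label, best_dist = label, dist
    return best_label
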