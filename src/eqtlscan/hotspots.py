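"""Regulatory-hotspot discovery.

A hotspot is a SNP that regulates many genes. Two definitions are
used, mirroring how cis and trans architecture differ:

* cis hotspot — a SNP with significant cis associations to at least 7
  unique genes (inclusive threshold).
* trans hotspot — a SNP whose count of significantly trans-regulated
  genes STRICTLY exceeds the 99th percentile (linear-interpolation
  convention) of the per-SNP regulated-gene count distribution.

Trans hotspot candidates are then vetted by permutation: sample labels
of the expression matrix are permuted jointly across genes (one shared
permutation per iteration — preserving genotype LD and the inter-gene
correlation structure that inflates per-SNP counts), the candidate
SNPs are rescanned against all genes with the trans pipeline, and the
permutation p-value is

    perm_p = (1 + #{iterations with permuted count >= observed}) / (B + 1)

which always lies on the grid {(k+1)/(B+1)} and never returns zero; at
B = 100,000 the minimum attainable value is ~1e-5. BH FDR across the
candidate list yields hotspot q-values; a trans hotspot that also has
a significant cis association is flagged as a shared cis+trans hub.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .errors import ConfigError, PipelineError
from .io import MISSING
from .association import bh_fdr, build_design, residualize, _align_samples

log = logging.getLogger(__name__)


def count_regulated_genes(
    records: pd.DataFrame, klass: str, fdr_max: float = 0.05
) -> pd.Series:
    """Per-SNP count of DISTINCT genes significantly regulated.

    Only SNPs with at least one significant record of the requested
    class appear in the output. Invariant to record order and to
    duplicated SNP-gene rows.
    """
    sig = records[(records["class"] == klass) & (records["fdr"] <= fdr_max)]
    counts = sig.groupby("snp_id")["gene_id"].nunique().sort_index()
    counts.name = "n_genes"
    return counts


def cis_hotspots(count_table: pd.Series, min_genes: int = 7) -> pd.DataFrame:
    """SNPs whose cis regulated-gene count reaches ``min_genes`` (inclusive)."""
    hits = count_table[count_table >= min_genes]
    return pd.DataFrame({
        "snp_id": hits.index,
        "class": "cis",
        "n_genes": hits.to_numpy(),
    }).reset_index(drop=True)


def trans_hotspot_cutoff(count_table: pd.Series, percentile: float = 99.0) -> float:
    """Percentile cutoff of the per-SNP regulated-gene count distribution.

    Linear interpolation between order statistics; hotspot membership
    is count STRICTLY greater than this value.
    """
    if len(count_table) == 0:
        raise PipelineError("trans hotspot cutoff undefined on an empty count table")
    return float(np.percentile(count_table.to_numpy(float), percentile))


def trans_hotspots(count_table: pd.Series, percentile: float = 99.0) -> pd.DataFrame:
    """Candidate trans hotspots: counts strictly above the percentile cutoff."""
    if len(count_table) == 0:
        return pd.DataFrame(columns=["snp_id", "class", "n_genes"])
    cutoff = trans_hotspot_cutoff(count_table, percentile)
    hits = count_table[count_table > cutoff]
    return pd.DataFrame({
        "snp_id": hits.index,
        "class": "trans",
        "n_genes": hits.to_numpy(),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    expression: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    hotspot_snps: list[str],
    B: int,
    config: PipelineConfig | None = None,
    seed: int | None = None,
):
    """Permutation p-values for trans-hotspot candidates.

    Each of the ``B`` iterations applies ONE shared permutation of the
    expression matrix's sample labels (Freedman-Lane style: residuals
    are permuted and re-projected off the covariates), rescans only the
    candidate SNPs against all genes with the trans pipeline — same
    emission threshold, BH against the number of trans pairs restricted
    to these SNPs — and records each candidate's permuted
    regulated-gene count. The observed count is computed with the same
    restricted construction, so observed and null statistics are
    exchangeable.

    Returns ``(result, perm_counts)``: a DataFrame with snp_id,
    n_genes (restricted observed count) and perm_p, plus the B x
    n_candidates matrix of permuted counts for diagnostics.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    if len(hotspot_snps) == 0:
        raise PipelineError("no hotspot candidates supplied")
    config = config or PipelineConfig()
    if 1.0 / (B + 1) > config.fdr_max:
        log.warning(
            "B=%d cannot reach perm_p below the FDR target %.3g "
            "(minimum attainable is %.3g)", B, config.fdr_max, 1.0 / (B + 1)
        )
    samples = _align_samples(expression, dosages, covariates)
    G = dosages.loc[samples, hotspot_snps].to_numpy().T.astype(float)
    keep = ~(G == MISSING).any(axis=0)
    if not keep.all():
        log.info(
            "permutation_test: dropping %d samples with missing calls "
            "at candidate SNPs", int((~keep).sum())
        )
        samples = [s for s, k in zip(samples, keep) if k]
        G = G[:, keep]
    X = build_design(covariates, samples)
    n, q = X.shape
    df = n - q - 1
    if df < 1:
        raise ConfigError("too few samples for the permutation scan")
    Q = np.linalg.qr(X)[0]

    E = expression[samples].to_numpy(float)
    En = E - (E @ Q) @ Q.T
    Gn = G - (G @ Q) @ Q.T
    gg = np.einsum("ij,ij->i", Gn, Gn)
    if np.any(gg <= 1e-12 * n):
        bad = [s for s, g2 in zip(hotspot_snps, gg) if g2 <= 1e-12 * n]
        raise PipelineError(f"zero genotype variance at candidate SNPs: {bad}")

    vsub = variants.set_index("snp_id").loc[hotspot_snps]
    g_chrom = genes.set_index("gene_id").loc[expression.index, "chrom"].astype(str).to_numpy()
    starts = genes.set_index("gene_id").loc[expression.index, "start"].to_numpy()
    ends = genes.set_index("gene_id").loc[expression.index, "end"].to_numpy()
    s_chrom = vsub["chrom"].astype(str).to_numpy()
    pos = vsub["pos"].to_numpy()
    same = g_chrom[:, None] == s_chrom[None, :]
    dist = np.maximum(0, np.maximum(starts[:, None] - pos[None, :], pos[None, :] - ends[:, None]))
    trans_mask = ~(same & (dist <= config.cis_window))
    m_restricted = int(trans_mask.sum())

    t_thresh = float(sps.t.ppf(1.0 - config.p_trans / 2.0, df))  # |t| above => p < p_trans

    def _counts(Er: np.ndarray) -> np.ndarray:
        ee = np.einsum("ij,ij->i", Er, Er)
        EG = Er @ Gn.T
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = EG / gg[None, :]
            sse = np.maximum(ee[:, None] - beta * EG, 0.0)
            se = np.sqrt(sse / df / gg[None, :])
            t = np.where(se > 0.0, np.abs(beta) / se, np.inf)
        emit = trans_mask & (t > t_thresh)
        out = np.zeros(len(hotspot_snps), dtype=int)
        if emit.any():
            gi, si = np.where(emit)
            p = 2.0 * sps.t.sf(t[gi, si], df)
            p = np.maximum(p, np.nextafter(0.0, 1.0))
            fdr = bh_fdr(p, m_restricted)
            sig = fdr <= config.fdr_max
            for k in range(len(hotspot_snps)):
                out[k] = len(set(gi[sig & (si == k)]))
        return out

    observed = _counts(En)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    perm_counts = np.zeros((B, len(hotspot_snps)), dtype=int)
    for b in range(B):
        perm = rng.permutation(n)
        Ep = En[:, perm]
        Ep -= (Ep @ Q) @ Q.T
        perm_counts[b] = _counts(Ep)

    exceed = (perm_counts >= observed[None, :]).sum(axis=0)
    perm_p = (1.0 + exceed) / (B + 1.0)
    result = pd.DataFrame({
        "snp_id": hotspot_snps,
        "n_genes": observed,
        "perm_p": perm_p,
    })
    return result, pd.DataFrame(perm_counts, columns=hotspot_snps)


def hotspot_fdr(perm_p, fdr_max: float = 0.05):
    """BH q-values across the hotspot candidates (m = #candidates).

    Returns ``(q, significant)`` with significance at q < fdr_max
    (strict).
    """
    perm_p = np.asarray(perm_p, dtype=float)
    if len(perm_p) == 0:
        return np.array([]), np.array([], dtype=bool)
    q = bh_fdr(perm_p)
    return q, q < fdr_max


def flag_shared_hubs(
    trans_hotspot_table: pd.DataFrame,
    cis_records: pd.DataFrame,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Mark trans hotspots that also carry a significant cis association."""
    cis_sig = set(
        cis_records.loc[cis_records["fdr"] <= fdr_max, "snp_id"]
    )
    out = trans_hotspot_table.copy()
    out["shared_hub"] = out["snp_id"].isin(cis_sig)
    return out
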