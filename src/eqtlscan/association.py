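"""The eQTL association engine.

Expression is regressed on allele dosage under an additive linear
model with covariates (intercept + age by default). The engine works
in matrix form: expression rows and dosage vectors are first projected
onto the orthogonal complement of the covariate space
(Frisch-Waugh-Lovell), after which every SNP-gene statistic reduces to
a correlation:

    r   = corr(e_resid, g_resid)
    t   = r * sqrt(df / (1 - r^2)),   df = n_eff - n_covariates - 1
    beta = <e_resid, g_resid> / <g_resid, g_resid>   (per allele copy)
    se  = |beta / t|
    var_explained = t^2 / (t^2 + df)

These are numerically identical to per-pair OLS of expression on
dosage + covariates. Genotypes enter as raw 0/1/2 dosages, so beta is
the change in normalized expression per copy of the ALT allele.

A pair is *cis* when the SNP lies on the gene's chromosome within
±100 kb of the gene body (inclusive), *trans* otherwise. cis and trans
are analyzed separately: records are emitted below per-class p-value
thresholds (0.02 cis, 1e-6 trans) and Benjamini-Hochberg FDR is
computed per class against the TOTAL number of tests in that class,
not just the emitted records. Samples with missing genotype calls are
dropped pairwise (per SNP), with the degrees of freedom reduced
accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .errors import AlignmentError, CollinearityError, ConfigError
from .io import ASSOC_COLUMNS, MISSING

log = logging.getLogger(__name__)

_P_FLOOR = np.nextafter(0.0, 1.0)  # report underflowed tails as the smallest subnormal


# ---------------------------------------------------------------------------
# Linear-algebra primitives
# ---------------------------------------------------------------------------

def residualize(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project each row of ``matrix`` off the covariate column space.

    ``matrix`` is (rows x n); ``covariates`` is the (n x q) design,
    which must include the intercept and be full rank. Residual rows
    are orthogonal to every covariate column.
    """
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise CollinearityError("covariate design is rank deficient")
    return M - (M @ Q) @ Q.T


@dataclass
class AssocStats:
    beta: float
    se: float
    t: float
    p: float
    var_explained: float
    ci95_low: float
    ci95_high: float


def assoc_stats(e_resid: np.ndarray, g_resid: np.ndarray, df: int) -> AssocStats:
    """Association statistics for one residualized SNP-gene pair.

    Returns all-NaN stats when the genotype has zero residual variance
    (the pair is flagged and excluded downstream).
    """
    if df < 1:
        raise ConfigError(f"degrees of freedom must be >= 1, got {df}")
    e = np.asarray(e_resid, dtype=float)
    g = np.asarray(g_resid, dtype=float)
    gg = float(g @ g)
    if gg == 0.0:
        nan = float("nan")
        return AssocStats(nan, nan, nan, nan, nan, nan, nan)
    ee = float(e @ e)
    eg = float(e @ g)
    beta = eg / gg
    if ee == 0.0:
        # constant expression: no association by definition
        return AssocStats(0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
    sse = max(ee - beta * eg, 0.0)
    with np.errstate(divide="ignore"):
        se = float(np.sqrt(sse / df / gg))
        t = beta / se if se > 0.0 else np.copysign(np.inf, beta)
    p = max(2.0 * float(sps.t.sf(abs(t), df)), _P_FLOOR)
    ve = (t * t) / (t * t + df) if np.isfinite(t) else 1.0
    tcrit = float(sps.t.ppf(0.975, df))
    return AssocStats(
        beta=beta, se=se, t=t, p=p,
        var_explained=min(ve, np.nextafter(1.0, 0.0)),
        ci95_low=beta - tcrit * se, ci95_high=beta + tcrit * se,
    )


def _block_stats(En, ee, Gn, gg, df):
    """Vectorized statistics for residualized blocks.

    En: genes x n (residualized expression); Gn: snps x n (residualized
    dosages); ee, gg the corresponding row sums of squares. Returns
    (beta, se, t, p, ve) arrays of shape genes x snps; columns with
    gg == 0 come out NaN.
    """
    EG = En @ Gn.T
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = EG / gg[None, :]
        sse = np.maximum(ee[:, None] - beta * EG, 0.0)
        se = np.sqrt(sse / df / gg[None, :])
        t = np.where(se > 0.0, beta / se, np.copysign(np.inf, beta))
        t = np.where(np.isnan(beta), np.nan, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isnan(t), np.nan, np.maximum(p, _P_FLOOR))
    with np.errstate(invalid="ignore"):
        ve = np.where(np.isfinite(t), (t * t) / (t * t + df), np.where(np.isnan(t), np.nan, 1.0))
    # constant expression rows: no association
    zero_e = ee == 0.0
    if zero_e.any():
        beta[zero_e], se[zero_e], t[zero_e] = 0.0, 0.0, 0.0
        p[zero_e], ve[zero_e] = 1.0, 0.0
    return beta, se, t, p, ve


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------

def classify_pair(snp_chrom, snp_pos: int, gene, cis_window: int = 100_000):
    """Classify one SNP-gene pair; returns ('cis'|'trans', distance).

    distance = 0 inside the gene body, else bp to the nearer gene edge;
    -1 denotes a cross-chromosome pair, where distance is undefined.
    A pair is cis iff same chromosome and distance <= cis_window
    (inclusive boundary).
    """
    if str(snp_chrom) != str(gene.chrom):
        return "trans", -1
    if gene.start <= snp_pos <= gene.end:
        return "cis", 0
    dist = min(abs(snp_pos - gene.start), abs(snp_pos - gene.end))
    return ("cis" if dist <= cis_window else "trans"), dist


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values against ``m_total`` tests.

    ``m_total`` may exceed ``len(p_values)`` when the supplied p-values
    are the smallest of a larger family (emission-thresholded scans):
    q_i = min over p_j >= p_i of m_total * p_j / rank_j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ConfigError(f"m_total ({m}) < number of p-values ({len(p)})")
    if len(p) == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, len(p) + 1)
    q_sorted = np.minimum(1.0, p[order] * m / ranks)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def _align_samples(expression, dosages, covariates):
    e_samples = list(expression.columns)
    if set(e_samples) != set(dosages.index) or set(e_samples) != set(covariates.index):
        raise AlignmentError(
            "expression, genotype and covariate sample sets differ"
        )
    return e_samples


def build_design(covariates: pd.DataFrame, samples) -> np.ndarray:
    """Intercept + every covariate column, in sample order."""
    cov = covariates.loc[samples]
    return np.column_stack([np.ones(len(samples))] + [cov[c].to_numpy(float) for c in cov.columns])


def scan(
    expression: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    config: PipelineConfig | None = None,
):
    """Run the full cis/trans eQTL scan.

    Returns ``(cis_records, trans_records, counts)`` where the record
    tables follow :data:`eqtlscan.io.ASSOC_COLUMNS` and ``counts``
    reports n_cis_tests, n_trans_tests and n_flagged (zero-variance
    pairs, counted as tests but never emitted). The conservation
    identity n_cis_tests + n_trans_tests = n_snps * n_genes holds on
    every run.
    """
    config = config or PipelineConfig()
    genes = genes.set_index("gene_id", drop=False).loc[expression.index].reset_index(drop=True)
    variants = variants.set_index("snp_id", drop=False).loc[dosages.columns].reset_index(drop=True)
    samples = _align_samples(expression, dosages, covariates)
    X = build_design(covariates, samples)
    n, q = X.shape
    E = expression[samples].to_numpy(float)
    G = dosages.loc[samples].to_numpy().T.astype(float)  # snps x samples
    miss = G == MISSING

    # pairwise cis/trans geometry (genes x snps)
    g_chrom = genes["chrom"].astype(str).to_numpy()
    s_chrom = variants["chrom"].astype(str).to_numpy()
    starts, ends = genes["start"].to_numpy(), genes["end"].to_numpy()
    pos = variants["pos"].to_numpy()
    same = g_chrom[:, None] == s_chrom[None, :]
    dist = np.maximum(0, np.maximum(starts[:, None] - pos[None, :], pos[None, :] - ends[:, None]))
    cis_mask = same & (dist <= config.cis_window)
    dist = np.where(same, dist, -1)

    n_genes, n_snps = E.shape[0], G.shape[0]
    n_cis_tests = int(cis_mask.sum())
    n_trans_tests = n_genes * n_snps - n_cis_tests

    beta = np.full((n_genes, n_snps), np.nan)
    se = np.full_like(beta, np.nan)
    tmat = np.full_like(beta, np.nan)
    pmat = np.full_like(beta, np.nan)
    vemat = np.full_like(beta, np.nan)
    tcrit = np.full(n_snps, np.nan)

    complete = ~miss.any(axis=1)
    df_full = n - q - 1
    if complete.any():
        if df_full < 1:
            raise ConfigError("too few samples for the covariate design")
        En = residualize(E, X)
        ee = np.einsum("ij,ij->i", En, En)
        Gn = residualize(G[complete], X)
        gg = np.einsum("ij,ij->i", Gn, Gn)
        gg = np.where(gg <= 1e-12 * n, 0.0, gg)  # flag zero residual variance
        with np.errstate(invalid="ignore"):
            b, s, t, p, ve = _block_stats(En, ee, Gn, np.where(gg == 0, np.nan, gg), df_full)
        cols = np.where(complete)[0]
        beta[:, cols], se[:, cols], tmat[:, cols] = b, s, t
        pmat[:, cols], vemat[:, cols] = p, ve
        tcrit[cols] = sps.t.ppf(0.975, df_full)

    # SNPs with missing calls: drop samples pairwise, per SNP
    for si in np.where(~complete)[0]:
        ok = ~miss[si]
        df_si = int(ok.sum()) - q - 1
        if df_si < 1:
            continue  # flagged: too few complete samples
        Xs = X[ok]
        try:
            En_s = residualize(E[:, ok], Xs)
            g_s = residualize(G[si, ok][None, :], Xs)
        except CollinearityError:
            continue
        ee_s = np.einsum("ij,ij->i", En_s, En_s)
        gg_s = np.einsum("ij,ij->i", g_s, g_s)
        gg_s = np.where(gg_s <= 1e-12 * ok.sum(), np.nan, gg_s)
        b, s, t, p, ve = _block_stats(En_s, ee_s, g_s, gg_s, df_si)
        beta[:, si], se[:, si], tmat[:, si] = b[:, 0], s[:, 0], t[:, 0]
        pmat[:, si], vemat[:, si] = p[:, 0], ve[:, 0]
        tcrit[si] = sps.t.ppf(0.975, df_si)

    n_flagged = int(np.isnan(pmat).sum())

    def _emit(mask, p_threshold, klass, m_total):
        with np.errstate(invalid="ignore"):
            sel = mask & (pmat < p_threshold) & ~np.isnan(pmat)
        gi, si = np.where(sel)
        rec = pd.DataFrame({
            "snp_id": variants["snp_id"].to_numpy()[si],
            "gene_id": genes["gene_id"].to_numpy()[gi],
            "beta": beta[gi, si],
            "se": se[gi, si],
            "t": tmat[gi, si],
            "p": pmat[gi, si],
            "fdr": bh_fdr(pmat[gi, si], m_total) if len(gi) else np.array([]),
            "class": klass,
            "distance": dist[gi, si],
            "var_explained": vemat[gi, si],
            "ci95_low": beta[gi, si] - tcrit[si] * se[gi, si],
            "ci95_high": beta[gi, si] + tcrit[si] * se[gi, si],
        })
        return rec.sort_values("p", kind="mergesort").reset_index(drop=True)[ASSOC_COLUMNS]

    cis_records = _emit(cis_mask, config.p_cis, "cis", n_cis_tests)
    trans_records = _emit(~cis_mask, config.p_trans, "trans", n_trans_tests)
    counts = {
        "n_cis_tests": n_cis_tests,
        "n_trans_tests": n_trans_tests,
        "n_flagged": n_flagged,
    }
    log.info(
        "scan: %d genes x %d SNPs; %d cis tests, %d trans tests, "
        "%d cis records, %d trans records",
        n_genes, n_snps, n_cis_tests, n_trans_tests,
        len(cis_records), len(trans_records),
    )
    return cis_records, trans_records, counts


# ---------------------------------------------------------------------------
# Gene-wise reduction and diagnostics
# ---------------------------------------------------------------------------

def _pos_from_snp_id(snp_id: str) -> int:
    return int(str(snp_id).split(":")[1].split("_")[0])


def top_per_gene(cis_records: pd.DataFrame, fdr_max: float = 0.05) -> pd.DataFrame:
    """One record per eGene: its lowest-FDR significant cis association.

    Ties on FDR break by smaller p, then smaller position, then
    lexicographic snp_id.
    """
    sig = cis_records[cis_records["fdr"] <= fdr_max].copy()
    if sig.empty:
        return sig[ASSOC_COLUMNS]
    sig["_pos"] = sig["snp_id"].map(_pos_from_snp_id)
    sig = sig.sort_values(
        ["gene_id", "fdr", "p", "_pos", "snp_id"], kind="mergesort"
    )
    top = sig.groupby("gene_id", sort=True).head(1).drop(columns="_pos")
    return top.reset_index(drop=True)[ASSOC_COLUMNS]


def qq_data(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot.

    expected_i = -log10((i - 0.5) / m) for the i-th smallest p-value.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if len(p) == 0:
        raise ConfigError("qq_data needs at least one p-value")
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p)
    return pd.DataFrame({"expected_quantile": expected, "observed_quantile": observed})
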