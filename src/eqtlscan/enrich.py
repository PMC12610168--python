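"""Over-representation analysis with kappa-score term clustering.

Terms (GO/KEGG-style gene sets, supplied as GMT files) are tested for
enrichment in a query gene list by the right-sided hypergeometric test
P(X >= k) given (N background genes, K term genes, n query genes, k in
the overlap), with Bonferroni and Benjamini-Hochberg corrections over
the tested terms. Functionally related terms are then grouped the way
ClueGO does at its default threshold: an edge joins two terms whose
Cohen's kappa over the binary gene-membership vectors reaches 0.4,
and clusters are the connected components with at least two terms
(isolated terms are left unclustered).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PipelineError

log = logging.getLogger(__name__)

KAPPA_UNDEFINED = float("nan")  # sentinel when chance agreement is exactly 1

ENRICH_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N", "p", "p_bonf", "p_bh", "cluster_id",
]


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: term_id <tab> term_name <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], set(g for g in parts[2:] if g))
    return terms


def write_gmt(path: str | Path, terms: dict[str, tuple[str, set[str]]]) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def hypergeom_enrich(
    query_genes,
    term_sets: dict[str, tuple[str, set[str]]],
    background,
) -> pd.DataFrame:
    """Right-sided hypergeometric enrichment of a query against terms.

    Terms are intersected with the background before testing; terms
    empty after intersection are skipped. p_bonf = min(1, p * m) over
    the m tested terms; BH q-values are reported alongside.
    """
    background = set(background)
    query = set(query_genes)
    if not query:
        raise PipelineError("empty query gene set")
    if not query <= background:
        raise PipelineError("query genes must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for tid, (name, genes) in term_sets.items():
        term = genes & background
        if not term:
            log.info("term %s empty after background intersection; skipped", tid)
            continue
        K = len(term)
        k = len(term & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((tid, name, k, K, n, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    m = len(out)
    out["p_bonf"] = np.minimum(1.0, out["p"] * m)
    from .association import bh_fdr

    out["p_bh"] = bh_fdr(out["p"].to_numpy())
    out["cluster_id"] = pd.NA
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def term_kappa(term_a: set[str], term_b: set[str], background) -> float:
    """Cohen's kappa between two terms' membership vectors.

    Both terms are read as binary indicators over the background:
    kappa = (po - pe) / (1 - pe) with po the fraction of genes on which
    the two indicators agree and pe the chance agreement from the
    marginals. Returns NaN when pe == 1 (both terms empty or both equal
    to the whole background).
    """
    bg = set(background)
    A, B = set(term_a) & bg, set(term_b) & bg
    N = len(bg)
    if N == 0:
        raise PipelineError("empty background")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    po = (a + d) / N
    pA, pB = len(A) / N, len(B) / N
    pe = pA * pB + (1 - pA) * (1 - pB)
    if pe == 1.0:
        return KAPPA_UNDEFINED
    return (po - pe) / (1.0 - pe)


def cluster_terms(
    records: pd.DataFrame,
    term_sets: dict[str, tuple[str, set[str]]],
    background,
    kappa_min: float = 0.4,
) -> pd.DataFrame:
    """Assign cluster ids by kappa-graph connected components.

    An edge joins terms with kappa >= ``kappa_min``; components with
    >= 2 terms get consecutive integer cluster ids (ordered by best
    member p-value), singletons stay unclustered (cluster_id <NA>).
    """
    out = records.copy()
    ids = [t for t in out["term_id"] if t in term_sets]
    G = nx.Graph()
    G.add_nodes_from(ids)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1:]:
            kap = term_kappa(term_sets[ta][1], term_sets[tb][1], background)
            if not np.isnan(kap) and kap >= kappa_min:
                G.add_edge(ta, tb)
    best_p = dict(zip(out["term_id"], out["p"]))
    comps = [sorted(c) for c in nx.connected_components(G) if len(c) >= 2]
    comps.sort(key=lambda c: min(best_p.get(t, 1.0) for t in c))
    assign: dict[str, int] = {}
    for cid, comp in enumerate(comps, start=1):
        for t in comp:
            assign[t] = cid
    out["cluster_id"] = out["term_id"].map(assign).astype("Int64")
    return out
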