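"""Hypergeometric GO over-representation tests with FDR control.

For a query set of n genes drawn from a universe of N genes of which K carry
a term, the over-representation p-value is the upper hypergeometric tail
P[X >= k] for the observed overlap k. Raw p-values are adjusted per
namespace by Benjamini–Hochberg FDR (a reimplementable stand-in for
service-specific correction schemes), the enrichment score is -log10(raw p),
and pairwise term-overlap counts supply edges for enrichment-network plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("MF", "BP", "CC")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    enrichment_score: float
    significant: bool


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    k: overlap between query and term; K: genes annotated with the term;
    n: query size; N: universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"invalid counts: k={k}, K={K}, n={n}, N={N} "
            "(need k <= min(K, n), K <= N, n <= N)"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene->GO TSV: columns gene_id, term_id, term_name, namespace."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name", "namespace"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def enrich(
    query_genes,
    annotation: pd.DataFrame,
    universe=None,
    threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """One hypergeometric test per annotated term (K >= 1).

    The universe defaults to all genes in the annotation table; query genes
    outside the universe are ignored. Adjustment is BH-FDR within each
    namespace; ``significant`` flags adjusted p below ``threshold``; the
    enrichment score is -log10 of the raw p.
    """
    if universe is None:
        universe = set(annotation["gene_id"])
    else:
        universe = set(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    n = len(query)

    ann = annotation[annotation["gene_id"].isin(universe)]
    results: list[EnrichmentResult] = []
    for (term_id, term_name, namespace), group in ann.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        term_genes = set(group["gene_id"])
        K = len(term_genes)
        k = len(term_genes & query)
        p = hypergeom_pvalue(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=term_name,
                namespace=namespace,
                k=k, K=K, n=n, N=N,
                p_value=p,
                p_adjusted=math.nan,
                enrichment_score=-math.log10(p) if p > 0 else math.inf,
                significant=False,
            )
        )
    for ns in sorted({r.namespace for r in results}):
        ns_results = [r for r in results if r.namespace == ns]
        adjusted = bh_adjust([r.p_value for r in ns_results])
        for r, adj in zip(ns_results, adjusted):
            r.p_adjusted = float(adj)
            r.significant = adj < threshold
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def term_overlap(term_gene_sets: dict[str, set]) -> list[tuple[str, str, int]]:
    """Pairwise term overlap counts |A ∩ B|; zero-overlap pairs omitted.

    Returns sorted (term_a, term_b, overlap) with term_a < term_b — the edge
    list of the term-overlap network.
    """
    terms = sorted(term_gene_sets)
    edges = []
    for i, ta in enumerate(terms):
        sa = set(term_gene_sets[ta])
        for tb in terms[i + 1 :]:
            k = len(sa & set(term_gene_sets[tb]))
            if k > 0:
                edges.append((ta, tb, k))
    return edges


def write_edge_list(edges: list[tuple[str, str, int]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["term_a", "term_b", "n_overlap"]).to_csv(
        path, sep="\t", index=False
    )
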