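"""QTL overlap annotation, hypergeometric enrichment and term grouping.

Candidate genes are annotated with the QTL intervals they overlap
(1-based inclusive on the same chromosome); enrichment of a trait or
annotation term in the query set is the hypergeometric upper tail of the
overlap count, BH-adjusted.  Redundant terms are grouped by average-linkage
clustering of 1 minus the Jaccard coefficient between their gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import bh_fdr
from .genomic import GeneModel
from .io import QtlRecord


@dataclass
class EnrichmentResult:
    term_or_trait: str
    k: int  # overlap count in query
    n: int  # query size
    K: int  # annotated count in background
    N: int  # background size
    p_value: float
    fdr: float = np.nan

    @property
    def enriched(self) -> bool:
        return bool(self.fdr < 0.05)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); 1.0 when k == 0."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotate_qtl_overlap(
    genes: list[GeneModel], qtls: list[QtlRecord]
) -> dict[str, list[QtlRecord]]:
    """Map each gene id to the QTL records its body overlaps."""
    by_chrom: dict[str, list[QtlRecord]] = {}
    for q in qtls:
        by_chrom.setdefault(q.interval.chrom, []).append(q)
    out: dict[str, list[QtlRecord]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        hits = [
            q
            for q in by_chrom.get(g.body.chrom, [])
            if g.body.overlaps(q.interval)
        ]
        out[g.gene_id] = sorted(hits, key=lambda q: (q.interval.start, q.qtl_id))
    return out


def qtl_enrichment(
    annotated: dict[str, list[QtlRecord]],
    qtl_db: list[QtlRecord],
    by: str = "trait",
) -> tuple[list[EnrichmentResult], pd.Series]:
    """Trait (or qtl_type) enrichment among the overlapped QTLs.

    For each category: k = overlapped QTLs of that category, n = all
    overlapped QTLs, K = database QTLs of that category, N = database size.
    Also returns the share of each qtl_type among the overlapped QTLs (the
    numbers behind the QTL-type pie chart).
    """
    hit_ids = {q.qtl_id for hits in annotated.values() for q in hits}
    hit_records = [q for q in qtl_db if q.qtl_id in hit_ids]
    n = len(hit_records)
    N = len(qtl_db)
    if n == 0:
        raise ValueError("no overlapping QTLs")
    key = (lambda q: q.trait) if by == "trait" else (lambda q: q.qtl_type)
    db_counts: dict[str, int] = {}
    for q in qtl_db:
        db_counts[key(q)] = db_counts.get(key(q), 0) + 1
    hit_counts: dict[str, int] = {}
    for q in hit_records:
        hit_counts[key(q)] = hit_counts.get(key(q), 0) + 1
    results = []
    for cat in sorted(hit_counts):
        if cat not in db_counts:
            continue
        k, K = hit_counts[cat], db_counts[cat]
        results.append(
            EnrichmentResult(cat, k, n, K, N, hypergeom_upper_tail(k, n, K, N))
        )
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    type_counts = pd.Series(
        [q.qtl_type for q in hit_records], dtype=str
    ).value_counts()
    type_share = (100.0 * type_counts / type_counts.sum()).sort_index()
    return results, type_share


def term_enrichment(
    query_genes: list[str],
    term_table: dict[str, set[str]],
    background_genes: list[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a query."""
    bg = set(background_genes)
    query = set(query_genes)
    if not query <= bg:
        raise ValueError("query genes must be a subset of the background")
    results = []
    for term in sorted(term_table):
        annotated = term_table[term] & bg
        if not annotated:
            continue
        k = len(query & annotated)
        results.append(
            EnrichmentResult(
                term,
                k,
                len(query),
                len(annotated),
                len(bg),
                hypergeom_upper_tail(k, len(query), len(annotated), len(bg)),
            )
        )
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


@dataclass
class TermSimilarityMatrix:
    terms: list[str]
    jaccard: np.ndarray  # symmetric, unit diagonal
    groups: pd.Series  # term -> integer group label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.jaccard, index=self.terms, columns=self.terms)


def jaccard_term_grouping(
    term_table: dict[str, set[str]],
    terms: list[str] | None = None,
    cut_k: int = 5,
) -> TermSimilarityMatrix:
    """Group terms by average-linkage clustering of 1 - Jaccard similarity.

    All annotated terms participate regardless of enrichment status.
    """
    terms = sorted(term_table) if terms is None else list(terms)
    if len(terms) < 2:
        raise ValueError("need >=2 terms to group")
    m = len(terms)
    jac = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = term_table[terms[i]], term_table[terms[j]]
            union = len(a | b)
            jac[i, j] = jac[j, i] = (len(a & b) / union) if union else 0.0
    dist = squareform(1.0 - jac, checks=False)
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(link, t=min(cut_k, m), criterion="maxclust")
    return TermSimilarityMatrix(terms, jac, pd.Series(labels, index=terms))


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                term_or_trait=r.term_or_trait,
                k=r.k,
                n=r.n,
                K=r.K,
                N=r.N,
                p_value=r.p_value,
                fdr=r.fdr,
                enriched=r.enriched,
            )
            for r in results
        ]
    )
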