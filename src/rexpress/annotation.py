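"""Term over-representation among enriched genes.

Enriched gene sets are joined against a flat gene→term annotation to produce
per-term member lists and counts, and each term is tested for
over-representation with the one-sided Fisher exact test: with a universe of
N genes, K annotated to the term, and n enriched genes, the p-value for
observing k enriched-and-annotated genes is the upper hypergeometric tail
P(X >= k), X ~ Hypergeom(N, K, n). Only over-representation is tested;
depletion is not reported. Terms carry a class (GO / pathway / TF); the TF
class doubles as the transcription-factor filter for enriched lists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationTable, GeneList

logger = logging.getLogger(__name__)

TERM_SUMMARY_COLUMNS = (
    "term_id",
    "term_name",
    "term_class",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "members",
)


def fisher_overrepresentation(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for X ~ Hypergeom(N, K, n).

    k: enriched genes annotated to the term; K: universe genes annotated to
    the term; n: enriched genes in the universe; N: universe size.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def summarize_terms(
    enriched: GeneList,
    annotation: AnnotationTable,
    universe: GeneList,
    term_class: str | None = None,
) -> pd.DataFrame:
    """Per-term counts, member lists, and Fisher over-representation p-values.

    Annotation terms are taken as a flat table (no GO-DAG propagation). Only
    terms with at least one enriched member are reported, sorted by p-value
    then term id. K and n are computed within the universe; enriched genes
    outside the universe are dropped with a logged warning.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    uni = universe.genes
    stray = enriched.genes - uni
    if stray:
        logger.warning(
            "%d enriched gene(s) outside the universe were ignored: %s",
            len(stray), sorted(stray)[:10],
        )
    hits = enriched.genes & uni
    N = len(uni)
    n = len(hits)

    rows = []
    terms = annotation.terms
    if term_class is not None:
        terms = terms[terms["term_class"] == term_class]
    for term_id in terms.index:
        annotated = annotation.genes_for_term(term_id) & uni
        members = annotated & hits
        k = len(members)
        if k == 0:
            continue
        K = len(annotated)
        p = fisher_overrepresentation(k, K, n, N)
        rows.append(
            (
                term_id,
                terms.loc[term_id, "term_name"],
                terms.loc[term_id, "term_class"],
                k,
                K,
                n,
                N,
                p,
                ",".join(sorted(members)),
            )
        )
    out = pd.DataFrame(rows, columns=list(TERM_SUMMARY_COLUMNS))
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
        drop=True
    )


def filter_transcription_factors(
    enriched: GeneList, annotation: AnnotationTable
) -> GeneList:
    """Subset of an enriched gene list annotated as transcription factors
    (any term of class ``TF``)."""
    tf_terms = set(annotation.terms_of_class("TF"))
    if not tf_terms:
        logger.warning("annotation contains no TF-class terms")
        return GeneList(label=f"{enriched.label}_TF", genes=frozenset())
    tf_genes = frozenset(
        g for g in enriched.genes if annotation.terms_for_gene(g) & tf_terms
    )
    return GeneList(label=f"{enriched.label}_TF", genes=tf_genes)
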