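"""Local gene-set over-representation of the stable differential gene list.

One-sided hypergeometric upper-tail test per term with Benjamini-Hochberg
correction across the terms of a collection.  With a background of N genes,
a term of K members and a query of n genes overlapping the term in x, the
p-value is P(X >= x) for X ~ Hypergeometric(N, K, n).  Terms with
p < 0.01 and FDR < 0.2 are reported as significant.

The background defaults to the universe the query was drawn from (e.g. all
genes carrying at least one enumerated event); over-representation is only
meaningful against the tested universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .count_test import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeom_overrep", "enrich"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    background_size: int
    background_genes: set[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.background_size <= 0:
            raise ValueError("background size must be positive")
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            if len(genes) > self.background_size:
                raise ValueError(f"gene set {term!r} exceeds the background size")


def hypergeom_overrep(x: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= x)."""
    if not (0 <= x <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent arguments: x={x}, K={K}, n={n}, N={N} "
            "(need 0 <= x <= min(K, n) <= N)"
        )
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(
    query_genes,
    collection: GeneSetCollection,
    p_max: float = 0.01,
    fdr_max: float = 0.2,
) -> pd.DataFrame:
    """Over-representation of *query_genes* in every term of the collection.

    Query genes outside the background (when the background gene list is
    known) are dropped with a logged count.  Returns one row per term sorted
    by p-value, with columns term, overlap, term_size, p_value, fdr,
    significant, overlapping_genes.
    """
    query = set(query_genes)
    if collection.background_genes is not None:
        dropped = query - collection.background_genes
        if dropped:
            logger.info("%d query genes outside the background dropped", len(dropped))
        query &= collection.background_genes
    if not query:
        raise ValueError("query is empty after background filtering")

    n = len(query)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        overlap = sorted(query & members)
        rows.append(
            {
                "term": term,
                "overlap": len(overlap),
                "term_size": len(members),
                "p_value": hypergeom_overrep(
                    len(overlap), len(members), n, collection.background_size
                ),
                "overlapping_genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    result["fdr"] = bh_fdr(result["p_value"])
    result["significant"] = (result["p_value"] < p_max) & (result["fdr"] < fdr_max)
    result = result.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return result[
        ["term", "overlap", "term_size", "p_value", "fdr", "significant", "overlapping_genes"]
    ]
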