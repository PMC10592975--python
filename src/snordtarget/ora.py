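"""Minimal over-representation analysis (ORA) over user-supplied term maps.

For a query gene set drawn from a declared universe, each term's
enrichment is scored with the one-sided (upper tail) hypergeometric
test, BH-adjusted across terms. The effect size is
``foldEnrichment = GeneRatio / BgRatio`` where GeneRatio is the in-term
fraction of the query and BgRatio the in-term fraction of the universe.
Results are ordered by adjusted p, then by descending fold enrichment.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_ora(
    query: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
    q_cutoff: float | None = None,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric ORA table (one row per tested term).

    Columns: term, k (query hits), term_size (in-universe), GeneRatio,
    BgRatio, foldEnrichment, pvalue, padj. Terms with fewer than
    ``min_term_size`` universe genes are skipped (degenerate cells);
    zero-overlap terms are reported with p = 1 and foldEnrichment 0.
    With ``q_cutoff`` set, rows with padj > q_cutoff are dropped after
    adjustment.
    """
    query, universe = set(query), set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    N, n = len(universe), len(query)
    rows = []
    for term in sorted(terms):
        term_genes = terms[term] & universe
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(query & term_genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 reported as p = 1
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        gene_ratio = k / n
        bg_ratio = K / N
        rows.append(
            dict(
                term=term,
                k=k,
                term_size=K,
                GeneRatio=gene_ratio,
                BgRatio=bg_ratio,
                foldEnrichment=gene_ratio / bg_ratio,
                pvalue=p,
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "term_size", "GeneRatio", "BgRatio",
                     "foldEnrichment", "pvalue", "padj"]
        )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out = out.sort_values(
        ["padj", "foldEnrichment"], ascending=[True, False]
    ).reset_index(drop=True)
    if q_cutoff is not None:
        out = out[out["padj"] <= q_cutoff].reset_index(drop=True)
    return out
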