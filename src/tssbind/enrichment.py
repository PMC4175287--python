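"""Term over-representation: fold enrichment with hypergeometric p-values.

Fold enrichment of a term in a gene set is the percentage of the set
annotated with the term divided by the percentage of the gene universe
annotated with it:

    fold = (|set ∩ term| / |set|) / (|universe ∩ term| / |universe|)

Significance is the hypergeometric upper tail of the observed overlap.
Result filtering drops terms that are too large (> 5000 genes by default),
not significant (p > 0.01 by default), or redundant (gene-set Jaccard >=
0.8 with a more significant term).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fold_enrichment", "filter_terms", "benjamini_hochberg"]


def fold_enrichment(
    gene_set: set[str],
    annotation: Mapping[str, Iterable[str]],
    universe: set[str],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term fold enrichment and hypergeometric upper-tail p.

    ``annotation`` maps term id -> gene ids. Genes outside ``universe`` are
    ignored; terms with no genes in the universe are skipped. The p-value is
    P[X >= overlap] for X hypergeometric with population |universe|,
    |term ∩ universe| successes and |gene_set| draws.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    extra = gene_set - universe
    if extra:
        raise ValueError(f"gene set not contained in universe: {sorted(extra)[:5]}")
    M = len(universe)
    n_set = len(gene_set)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        n_term = len(term_genes)
        if n_term == 0:
            continue
        overlap = len(term_genes & gene_set)
        fold = (overlap / n_set) / (n_term / M)
        p = float(stats.hypergeom.sf(overlap - 1, M, n_term, n_set))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "term_size": n_term,
                "overlap": overlap,
                "fold_enrichment": fold,
                "p": p,
                "genes": frozenset(term_genes),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["p", "term_id"]).reset_index(drop=True)
    return df


def filter_terms(
    results: pd.DataFrame,
    p_threshold: float = 0.01,
    max_term_size: int = 5000,
    redundancy_jaccard: float = 0.8,
) -> pd.DataFrame:
    """Apply the size, significance and redundancy filters.

    Among any pair of surviving terms whose universe gene sets have Jaccard
    index >= ``redundancy_jaccard``, only the smaller-p term (ties by term
    id) is kept.
    """
    if results.empty:
        return results
    df = results[
        (results["term_size"] <= max_term_size) & (results["p"] <= p_threshold)
    ].copy()
    df = df.sort_values(["p", "term_id"]).reset_index(drop=True)
    keep = []
    kept_sets: list[frozenset] = []
    for _, row in df.iterrows():
        genes = row["genes"]
        redundant = any(
            len(genes & prev) / len(genes | prev) >= redundancy_jaccard
            for prev in kept_sets
        )
        if not redundant:
            keep.append(row)
            kept_sets.append(genes)
    return pd.DataFrame(keep).reset_index(drop=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional output column; no filter uses it)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
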