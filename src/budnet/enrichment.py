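"""Local hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N, a set covering K universe
genes, and an observed overlap of k, the enrichment p-value is the upper
tail P(X >= k) of Hypergeometric(N, K, n), summed exactly in log space.
Benjamini-Hochberg correction runs across the tested sets; sets are size-
filtered after intersection with the declared universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .diffexp import adjust_bh
from .io_formats import PathwayDB

__all__ = ["hypergeom_pvalue", "gene_ratio", "enrich"]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), exact in log space."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def gene_ratio(k: int, K: int) -> float:
    """Fraction of a pathway's genes hit by the query: k/K."""
    if K < 1:
        raise ValueError("pathway size K must be >= 1")
    if not 0 <= k <= K:
        raise ValueError("overlap k must lie in [0, K]")
    return k / K


def enrich(query: list[str], db: PathwayDB, universe: list[str],
           min_size: int = 10, max_size: int = 500,
           alpha: float = 0.01) -> pd.DataFrame:
    """Over-representation table for a query gene list.

    Sets are intersected with the (deduplicated) universe and tested only if
    their effective size lies in [min_size, max_size]. Rows with p-value
    strictly below ``alpha`` are returned, sorted by gene_ratio descending
    then p-value ascending. padj is BH across all tested sets.
    """
    if min_size > max_size:
        raise ValueError("min_size exceeds max_size")
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe "
                      "dropped")
    q_set = {g for g in q if g in uni_set}
    if not q_set:
        raise ValueError("query empty after restricting to the universe")
    if len(db) == 0:
        raise ValueError("empty pathway collection")
    N = len(uni_set)
    n = len(q_set)
    rows = []
    for name, genes in db.sets.items():
        members = set(genes) & uni_set
        K = len(members)
        if not (min_size <= K <= max_size):
            continue
        overlap = sorted(members & q_set)
        k = len(overlap)
        rows.append({
            "set_name": name,
            "overlap_k": k,
            "set_size_K": K,
            "query_n": n,
            "universe_N": N,
            "pvalue": hypergeom_pvalue(k, K, n, N),
            "gene_ratio": gene_ratio(k, K),
            "overlap_genes": ",".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=["set_name", "overlap_k", "set_size_K",
                                     "query_n", "universe_N", "pvalue", "padj",
                                     "gene_ratio", "overlap_genes"])
    table = pd.DataFrame(rows)
    table["padj"] = adjust_bh(table["pvalue"].to_numpy())
    table = table[table["pvalue"] < alpha]
    table = table.sort_values(["gene_ratio", "pvalue", "set_name"],
                              ascending=[False, True, True], ignore_index=True)
    return table[["set_name", "overlap_k", "set_size_K", "query_n",
                  "universe_N", "pvalue", "padj", "gene_ratio",
                  "overlap_genes"]]
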