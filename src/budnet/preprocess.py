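"""Probe-to-gene collapse, median-of-ratios normalization, and ITBCC
tumor-budding categorization.

Collapse precedes normalization: when several probes target one gene, the
probe with the largest raw mean count is kept verbatim (selection, not
aggregation), ties broken by lexicographically smallest probe id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "collapse_probes",
    "size_factors",
    "normalize",
    "categorize_budding",
]


@dataclass
class NormalizedMatrix:
    """Depth-normalized counts: raw counts divided column-wise by size factors."""

    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if (self.values < 0).any():
            raise ValueError("normalized values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_symbols,
                            columns=self.sample_ids)

    def subset(self, genes: list[str]) -> np.ndarray:
        idx = pd.Index(self.gene_symbols)
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return self.values[idx.get_indexer(genes), :]


def collapse_probes(m: CountMatrix) -> CountMatrix:
    """Collapse a probe-level matrix to gene level by the max-mean rule.

    For each gene symbol measured by multiple probes, the probe row with the
    maximal raw mean count is kept unchanged; mean ties keep the probe with
    the lexicographically smallest id, making the collapse deterministic.
    """
    if any(s == "" or s is None for s in m.gene_symbols):
        raise ValueError("every probe needs a gene symbol to collapse")
    means = m.counts.mean(axis=1)
    order = sorted(range(m.n_genes),
                   key=lambda i: (m.gene_symbols[i], -means[i], m.row_ids[i]))
    keep: dict[str, int] = {}
    for i in order:
        keep.setdefault(m.gene_symbols[i], i)
    rows = sorted(keep.values(), key=lambda i: m.gene_symbols[i])
    symbols = [m.gene_symbols[i] for i in rows]
    return CountMatrix(
        row_ids=symbols,
        gene_symbols=symbols,
        sample_ids=list(m.sample_ids),
        counts=m.counts[rows, :],
        level="gene",
    )


def size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes of
    count_gj / geometric_mean_g, taken over genes expressed (count > 0) in
    every sample so the geometric mean is positive.
    """
    counts = m.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot compute size factors: no gene has nonzero "
                         "counts in all samples")
    sub = counts[positive, :]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def normalize(m: CountMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """Divide each sample column by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.n_samples,):
        raise ValueError("need exactly one size factor per sample")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return NormalizedMatrix(
        gene_symbols=list(m.gene_symbols),
        sample_ids=list(m.sample_ids),
        values=m.counts / factors,
        size_factors=factors,
    )


def categorize_budding(buds: int) -> str:
    """ITBCC category from a high-power-field bud count.

    0-4 buds -> low, 5-9 -> intermediate, >=10 -> high.
    """
    if buds < 0 or int(buds) != buds:
        raise ValueError("bud count must be a nonnegative integer")
    if buds <= 4:
        return "low"
    if buds <= 9:
        return "intermediate"
    return "high"
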