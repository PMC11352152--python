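"""Mutual-information screening of genes against the binary tumor-budding
class.

MI(X, Y) = H(X) + H(Y) - H(X, Y) in natural-log units (nats), computed on
discretized normalized expression. With 12 high and 3 low samples the class
entropy H(Y) = -(0.8 ln 0.8 + 0.2 ln 0.2) = 0.5004 nats is the ceiling any
gene can reach, attained exactly by genes whose expression perfectly
separates the classes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleAnnotation
from .preprocess import NormalizedMatrix

__all__ = [
    "discretize",
    "entropy",
    "joint_entropy",
    "mi_score",
    "mi_table",
    "select_top_mi",
    "default_n_bins",
]

_METHODS = ("equal_width", "equal_frequency", "distinct")
TIE_TOL = 1e-9


def default_n_bins(values: np.ndarray) -> int:
    """Sturges-like default: min(ceil(log2 n) + 1, number of distinct values)."""
    n = len(values)
    distinct = len(np.unique(values))
    return max(2, min(int(math.ceil(math.log2(max(n, 2)))) + 1, distinct))


def discretize(values: np.ndarray, method: str = "equal_width",
               n_bins: int | None = None) -> np.ndarray:
    """Map per-sample real values to integer category labels.

    equal_width uses uniform bin edges over [min, max]; equal_frequency puts
    edges at empirical quantiles with duplicate edges collapsed (so the
    category count never exceeds n_bins); distinct gives each unique value
    its own category. A constant vector yields a single category.
    """
    values = np.asarray(values, dtype=float)
    if method not in _METHODS:
        raise ValueError(f"unknown discretization method {method!r}")
    if method == "distinct":
        return np.unique(values, return_inverse=True)[1]
    if n_bins is None:
        n_bins = default_n_bins(values)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2 for binning methods")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return np.zeros(len(values), dtype=np.int64)
    if method == "equal_width":
        interior = np.linspace(lo, hi, n_bins + 1)[1:-1]
    else:  # equal_frequency: interior quantile edges, duplicates collapsed
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        interior = np.unique(np.quantile(values, qs))
    labels = np.searchsorted(interior, values, side="right")
    return labels.astype(np.int64)


def entropy(labels: np.ndarray) -> float:
    """Natural-log entropy of the empirical label frequencies (0 log 0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return float(stats.entropy(counts))


def joint_entropy(labels_x: np.ndarray, labels_y: np.ndarray) -> float:
    """Natural-log entropy of the empirical joint distribution."""
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    if labels_x.shape != labels_y.shape:
        raise ValueError("joint entropy requires equal-length vectors")
    _, xi = np.unique(labels_x, return_inverse=True)
    _, yi = np.unique(labels_y, return_inverse=True)
    joint = xi.astype(np.int64) * (yi.max() + 1) + yi
    _, counts = np.unique(joint, return_counts=True)
    return float(stats.entropy(counts))


def mi_score(gene_values: np.ndarray, class_labels: np.ndarray,
             method: str = "equal_width", n_bins: int | None = None) -> float:
    """MI between a gene's discretized expression and the binary class, in nats.

    Clipped at 0 to absorb floating-point negatives; bounded above by
    min(H(X), H(Y)).
    """
    gene_values = np.asarray(gene_values, dtype=float)
    class_labels = np.asarray(class_labels)
    if len(gene_values) != len(class_labels):
        raise ValueError("gene values and class labels differ in length")
    if len(gene_values) < 2:
        raise ValueError("need at least two samples")
    if len(np.unique(class_labels)) < 2:
        raise ValueError("both classes must be present")
    x = discretize(gene_values, method=method, n_bins=n_bins)
    mi = entropy(x) + entropy(class_labels) - joint_entropy(x, class_labels)
    return max(mi, 0.0)


def mi_table(norm: NormalizedMatrix, annotation: SampleAnnotation,
             method: str = "equal_width", n_bins: int | None = None
             ) -> pd.DataFrame:
    """Score every gene; returns (gene, mi_score, n_bins_used) sorted descending."""
    labeled = annotation.labeled()
    idx = pd.Index(norm.sample_ids)
    cols = idx.get_indexer(labeled["sample_id"])
    if (cols < 0).any():
        missing = labeled["sample_id"][cols < 0].tolist()
        raise ValueError(f"annotated samples absent from matrix: {missing}")
    y = labeled["class_label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rows = []
    for g, vals in zip(norm.gene_symbols, norm.values[:, cols]):
        nb = n_bins if n_bins is not None else default_n_bins(vals)
        rows.append((g, mi_score(vals, y, method=method, n_bins=nb),
                     min(nb, len(np.unique(vals)))))
    out = pd.DataFrame(rows, columns=["gene", "mi_score", "n_bins_used"])
    return out.sort_values(["mi_score", "gene"], ascending=[False, True],
                           ignore_index=True)


def select_top_mi(table: pd.DataFrame, mode: str = "max_ties",
                  k: int | None = None) -> list[str]:
    """Pick the top-scoring genes.

    max_ties: every gene within TIE_TOL of the maximum score (the study-style
    tie set). top_k: the k highest scores, with boundary ties all included.
    """
    if table.empty:
        raise ValueError("MI table is empty")
    scores = table["mi_score"].to_numpy(dtype=float)
    if mode == "max_ties":
        cut = scores.max() - TIE_TOL
        return table.loc[scores >= cut, "gene"].tolist()
    if mode == "top_k":
        if k is None or k <= 0:
            raise ValueError("top_k mode needs k >= 1")
        if k >= len(scores):
            return table["gene"].tolist()
        ordered = np.sort(scores)[::-1]
        cut = ordered[k - 1] - TIE_TOL
        return table.loc[scores >= cut, "gene"].tolist()
    raise ValueError(f"unknown selection mode {mode!r}")
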