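"""Quantitative evaluation of a selected gene panel: sample-correlation
structure, PCA projection, and a silhouette-based class-separation score.

All three views work on log2(value + 1)-transformed normalized expression
restricted to the panel, quantifying how well a panel's expression profile
clusters low- versus high-budding samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io_formats import SampleAnnotation
from .preprocess import NormalizedMatrix

__all__ = [
    "PanelEvaluation",
    "sample_correlation",
    "pca_project",
    "separation_score",
    "evaluate_panel",
]


@dataclass
class PanelEvaluation:
    panel: list[str]
    correlation_matrix: pd.DataFrame
    pc_coordinates: pd.DataFrame  # columns PC1, PC2 + explained variance attrs
    explained_variance: tuple[float, float]
    separation_score: float


def _log_panel(m: NormalizedMatrix, panel: list[str]) -> np.ndarray:
    if len(panel) < 2:
        raise ValueError("panel needs at least two genes")
    return np.log2(m.subset(list(panel)) + 1.0)


def sample_correlation(m: NormalizedMatrix, panel: list[str]) -> pd.DataFrame:
    """Pearson correlation between sample columns on the log2(x+1) panel."""
    x = _log_panel(m, panel)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [m.sample_ids[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant panel expression in sample(s) {bad}; "
                         "correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=m.sample_ids, columns=m.sample_ids)


def pca_project(m: NormalizedMatrix, panel: list[str]
                ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Top-2 PCA of standardized log2(x+1) sample vectors.

    Genes are z-scored across samples (constant genes contribute zero), and
    the sign of each component is fixed so its largest-magnitude loading is
    positive, making repeated runs identical. If the data have rank < 2 the
    second component is zeroed with a warning.
    """
    x = _log_panel(m, panel).T  # samples x genes
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least three samples")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe
    rank = np.linalg.matrix_rank(z - z.mean(axis=0))
    n_comp = 2 if rank >= 2 else 1
    if n_comp < 2:
        warnings.warn("panel expression has rank < 2; second component zeroed")
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(z)
    loadings = pca.components_
    for c in range(n_comp):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            coords[:, c] *= -1
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
        ev = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        ev = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    out = pd.DataFrame(coords, index=m.sample_ids, columns=["PC1", "PC2"])
    return out, ev


def separation_score(points: np.ndarray, class_labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean) of the two budding classes.

    A class with a single member contributes the conventional silhouette of
    0 for that sample (flagged with a warning).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(class_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("both classes must be present")
    if (counts == 1).any():
        warnings.warn("a class has a single member; its silhouette is 0 by "
                      "convention")
    return float(silhouette_score(points, labels, metric="euclidean"))


def evaluate_panel(m: NormalizedMatrix, panel: list[str],
                   annotation: SampleAnnotation) -> PanelEvaluation:
    """Full panel report restricted to class-labeled samples."""
    labeled = annotation.labeled()
    idx = pd.Index(m.sample_ids)
    cols = idx.get_indexer(labeled["sample_id"])
    if (cols < 0).any():
        raise ValueError("annotated samples absent from matrix")
    sub = NormalizedMatrix(
        gene_symbols=list(m.gene_symbols),
        sample_ids=labeled["sample_id"].tolist(),
        values=m.values[:, cols],
        size_factors=m.size_factors[cols],
    )
    corr = sample_correlation(sub, panel)
    coords, ev = pca_project(sub, panel)
    y = labeled["class_label"].to_numpy(dtype=int)
    score = separation_score(np.log2(sub.subset(list(panel)) + 1.0).T, y)
    return PanelEvaluation(panel=list(panel), correlation_matrix=corr,
                           pc_coordinates=coords, explained_variance=ev,
                           separation_score=score)
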