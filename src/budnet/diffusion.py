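"""Seed-set construction and regularized-Laplacian network diffusion.

Seeds are the genes found by BOTH the differential-expression test and the
mutual-information screen. With L = D - W the weighted graph Laplacian, the
regularized Laplacian kernel is K = (I + alpha*L)^-1 and the diffusion score
is S = K.y for the binary seed indicator y. Because L has zero row sums,
sum(S) = sum(y): the kernel redistributes the seed mass without creating or
destroying it, and all scores are nonnegative (I + alpha*L is an M-matrix).

The kernel is never materialized as a dense inverse; scores come from a
conjugate-gradient solve of the sparse SPD system (I + alpha*L) s = y.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg

from .io_formats import PPINetwork

__all__ = [
    "SeedSet",
    "KernelSystem",
    "build_seed_set",
    "build_kernel_system",
    "diffuse",
    "percentile_cutoff",
]


@dataclass
class SeedSet:
    """DEG ∩ MI intersection split by network membership."""

    genes: list[str]
    matched: list[str]
    unmatched: list[str]


@dataclass
class KernelSystem:
    """Assembled sparse SPD system A = I + alpha*L with its node order."""

    nodes: list[str]
    matrix: sp.csr_matrix
    alpha: float


def build_seed_set(degs: list[str], mi_genes: list[str],
                   network: PPINetwork) -> SeedSet:
    """Intersect the DEG and MI gene lists and match them against the network."""
    genes = sorted(set(degs) & set(mi_genes))
    if not genes:
        raise ValueError("no seeds: DEG and MI gene sets do not overlap; "
                         "relax thresholds")
    in_net = set(network.graph.nodes)
    matched = [g for g in genes if g in in_net]
    unmatched = [g for g in genes if g not in in_net]
    if unmatched:
        warnings.warn(f"{len(unmatched)} seed gene(s) absent from the network "
                      f"and excluded from diffusion: {unmatched}")
    return SeedSet(genes=genes, matched=matched, unmatched=unmatched)


def build_kernel_system(network: PPINetwork, alpha: float = 1.0,
                        weighted: bool = True) -> KernelSystem:
    """Assemble (I + alpha*L) over a fixed (sorted) node order.

    alpha = 0 is permitted and gives the identity (scores = seed indicator).
    ``weighted=False`` ignores edge confidences and uses the 0/1 adjacency.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    nodes = network.node_ids
    lap = nx.laplacian_matrix(network.graph, nodelist=nodes,
                              weight="weight" if weighted else None)
    lap = sp.csr_matrix(lap, dtype=float)
    a_mat = (sp.identity(len(nodes), format="csr") + alpha * lap).tocsr()
    return KernelSystem(nodes=nodes, matrix=a_mat, alpha=float(alpha))


def _solve_spd(a_mat: sp.csr_matrix, y: np.ndarray, tol: float = 1e-10
               ) -> np.ndarray:
    """Diagonally preconditioned conjugate-gradient solve of A s = y."""
    diag = a_mat.diagonal()
    precond = LinearOperator(a_mat.shape, matvec=lambda v: v / diag)
    s, info = cg(a_mat, y, rtol=tol, atol=0.0, M=precond,
                 maxiter=10 * a_mat.shape[0])
    if info != 0:
        residual = float(np.linalg.norm(a_mat @ s - y))
        raise RuntimeError(f"CG did not converge (info={info}, "
                           f"residual={residual:.3e})")
    return s


def diffuse(network: PPINetwork, seeds: SeedSet, alpha: float = 1.0,
            weighted: bool = True) -> pd.DataFrame:
    """Diffusion scores for every node from the matched seed indicator.

    Returns a table (node, score, is_seed, rank) sorted by descending score,
    ties broken by node id; ranks start at 1.
    """
    if not seeds.matched:
        raise ValueError("no matched seeds in the network")
    system = build_kernel_system(network, alpha=alpha, weighted=weighted)
    pos = {n: i for i, n in enumerate(system.nodes)}
    y = np.zeros(len(system.nodes))
    for g in seeds.matched:
        y[pos[g]] = 1.0
    scores = _solve_spd(system.matrix, y)
    out = pd.DataFrame({
        "node": system.nodes,
        "score": scores,
        "is_seed": [n in set(seeds.matched) for n in system.nodes],
    })
    out = out.sort_values(["score", "node"], ascending=[False, True],
                          ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def percentile_cutoff(result: pd.DataFrame, percentile: float = 99.0,
                      exclude_seeds: bool = True) -> list[str]:
    """Top-percentile candidate list from a diffusion table.

    The quota is ceil((1 - percentile/100) * n_total) where n_total counts
    every network node. With seed exclusion on (default) the quota is filled
    with the highest-scoring non-seed nodes — e.g. the 99th percentile of a
    19,038-node network yields ceil(190.38) = 191 candidates. Boundary ties
    are broken by node id (the table is already sorted that way).
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie strictly between 0 and 100")
    n_total = len(result)
    # (100 - p) * n / 100 avoids 1 - p/100 float noise at the quota boundary
    quota = math.ceil((100.0 - percentile) * n_total / 100.0)
    pool = result[~result["is_seed"]] if exclude_seeds else result
    if quota > len(pool):
        warnings.warn(f"quota {quota} exceeds the {len(pool)} available "
                      "nodes; returning all of them")
        quota = len(pool)
    return pool["node"].head(quota).tolist()
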