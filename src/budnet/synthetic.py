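"""Synthetic data with the statistical structure the pipeline assumes.

Emulates the study design the analysis targets: a small, imbalanced cohort
(default 12 high- vs 3 low-budding samples), negative-binomial counts with
per-sample depth factors, a planted fraction of differentially expressed
genes, a handful of planted perfect class separators (the genes that reach
the mutual-information ceiling H(Y)), a scale-free protein-interaction
network, and pathway collections enriched around the planted seeds. Every
generator draws from one explicit integer seed and keeps no global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import CountMatrix, PathwayDB, PPINetwork, SampleAnnotation

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_network",
    "simulate_pathways",
]


@dataclass
class SimulationTruth:
    """Ground truth planted by the generators."""

    de_genes: dict[str, float]  # gene -> true log2 fold change (high/low)
    separator_genes: list[str]
    seed_genes: list[str]
    enriched_sets: list[str] = field(default_factory=list)
    rng_seed: int = 0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with variance mu + dispersion*mu^2; dispersion -> 0
    degrades to Poisson."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = disp < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        r = 1.0 / disp[~poisson]
        p = r / (r + mean[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def simulate_counts(n_genes: int = 2000, n_high: int = 12, n_low: int = 3,
                    de_fraction: float = 0.05, lfc_location: float = 2.5,
                    dispersion: float = 0.1,
                    depth_range: tuple[float, float] = (0.5, 2.0),
                    n_separators: int = 7, rng_seed: int = 0,
                    per_gene_dispersion: bool = False
                    ) -> tuple[CountMatrix, SampleAnnotation, SimulationTruth]:
    """NB count matrix with planted DE genes and perfect class separators.

    count_gj ~ NB(mean = s_j * q_gc, dispersion) with size factors s_j
    log-uniform over ``depth_range`` and class-specific means q_gc. A
    de_fraction of genes carries a symmetric log2 effect drawn around
    ``lfc_location`` with random sign. ``n_separators`` genes (a subset of
    the DE genes) are planted as perfect separators: exactly zero in one
    class and tightly clustered high values in the other, so their value
    ranges never overlap and they attain the MI ceiling H(Y).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if n_high < 2:
        raise ValueError("need at least two high-class samples")
    if n_low < 1:
        raise ValueError("need at least one low-class sample")
    if n_low < 2:
        warnings.warn("n_low < 2: dispersion estimation will rely on the "
                      "high class only")
    rng = np.random.default_rng(rng_seed)
    n_samples = n_high + n_low
    genes = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"H{j + 1:02d}" for j in range(n_high)] + \
                 [f"L{j + 1:02d}" for j in range(n_low)]
    y = np.array([1] * n_high + [0] * n_low)

    lo, hi = depth_range
    if not (0 < lo <= hi):
        raise ValueError("depth_range must be positive and ordered")
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    base = rng.lognormal(mean=np.log(100.0), sigma=1.2, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    if n_separators > n_de:
        raise ValueError("n_separators cannot exceed the number of DE genes")
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    lfc = sign * np.abs(rng.normal(lfc_location, 0.25, size=n_de))
    sep_idx = de_idx[:n_separators]

    mean_high = base.copy()
    mean_low = base.copy()
    mean_high[de_idx] = base[de_idx] * 2.0 ** (lfc / 2.0)
    mean_low[de_idx] = base[de_idx] * 2.0 ** (-lfc / 2.0)

    if per_gene_dispersion:
        disp = rng.gamma(shape=2.0, scale=dispersion / 2.0, size=n_genes)
    else:
        disp = np.full(n_genes, float(dispersion))

    mu = np.where(y[None, :] == 1, mean_high[:, None], mean_low[:, None]) * s
    counts = _nb_draw(rng, mu, disp[:, None])

    # Perfect separators: zero counts in one class, tightly clustered
    # Poisson(s_j * q) values (floored at 1) in the other, q >= 500 so that
    # the normalized within-class spread stays far from zero under any
    # monotone binning.
    sep_lfc = lfc[:n_separators]
    for row, this_lfc in zip(sep_idx, sep_lfc):
        q = max(float(base[row]), 500.0)
        hot = y == 1 if this_lfc > 0 else y == 0
        vals = np.zeros(n_samples, dtype=np.int64)
        vals[hot] = np.maximum(rng.poisson(s[hot] * q), 1)
        counts[row] = vals

    cm = CountMatrix(row_ids=genes, gene_symbols=list(genes),
                     sample_ids=sample_ids, counts=counts, level="gene")
    ann = SampleAnnotation(pd.DataFrame({
        "sample_id": sample_ids,
        "tb_level": np.where(y == 1, "high", "low"),
        "class_label": y.astype(float),
    }))
    truth = SimulationTruth(
        de_genes={genes[i]: float(l) for i, l in zip(de_idx, lfc)},
        separator_genes=sorted(genes[i] for i in sep_idx),
        seed_genes=sorted(genes[i] for i in sep_idx),
        rng_seed=rng_seed,
    )
    return cm, ann, truth


def simulate_network(n_nodes: int, model: str = "barabasi_albert",
                     params: dict | None = None, rng_seed: int = 0,
                     node_names: list[str] | None = None) -> PPINetwork:
    """Connected undirected graph with confidence weights in (0.4, 1.0].

    barabasi_albert (default, m edges per new node) gives the scale-free
    degree structure typical of protein-interaction networks; a
    stochastic_block model (params: sizes, p) plants community structure,
    keeping the largest component with a warning if disconnected.
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    params = dict(params or {})
    rng = np.random.default_rng(rng_seed)
    nx_seed = int(rng.integers(0, 2 ** 31 - 1))
    if model == "barabasi_albert":
        m = int(params.get("m", 3))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=nx_seed)
    elif model == "stochastic_block":
        sizes = params.get("sizes")
        p = params.get("p")
        if sizes is None or p is None:
            raise ValueError("stochastic_block needs 'sizes' and 'p'")
        g = nx.stochastic_block_model(sizes, p, seed=nx_seed)
        g = nx.Graph(g)  # drop block metadata/multiedges
        if not nx.is_connected(g):
            comp = max(nx.connected_components(g), key=len)
            warnings.warn("stochastic block graph disconnected; keeping the "
                          f"largest component ({len(comp)}/{g.number_of_nodes()}"
                          " nodes)")
            g = g.subgraph(comp).copy()
    else:
        raise ValueError(f"unknown network model {model!r}")
    if node_names is not None:
        if len(node_names) < g.number_of_nodes():
            raise ValueError("not enough node names supplied")
        mapping = {old: node_names[i] for i, old in enumerate(sorted(g.nodes))}
        g = nx.relabel_nodes(g, mapping)
    else:
        g = nx.relabel_nodes(g, {old: f"N{old:05d}" for old in g.nodes})
    for a, b in g.edges:
        g[a][b]["weight"] = float(1.0 - rng.uniform(0.0, 0.6))  # (0.4, 1.0]
    return PPINetwork(g)


def simulate_pathways(network: PPINetwork, seed_genes: list[str],
                      n_sets: int = 50, size_range: tuple[int, int] = (10, 50),
                      n_enriched: int = 3, rng_seed: int = 0) -> PathwayDB:
    """Gene-set collection with ``n_enriched`` sets planted around the seeds.

    Planted sets contain the seed genes themselves plus members drawn from
    the seeds' graph neighborhood (1-hop preferred, then 2-hop) until >= 70%
    (target 80%) of the set lies within 2 hops of a seed; the remainder and
    every non-planted set are uniform random draws from the node universe.
    Set sizes are uniform within ``size_range``.
    """
    nodes = network.node_ids
    missing = sorted(set(seed_genes) - set(nodes))
    if missing:
        raise ValueError(f"seed genes absent from network: {missing}")
    lo, hi = size_range
    if lo < 1 or lo > hi:
        raise ValueError("invalid size_range")
    if hi > len(nodes):
        raise ValueError("size_range exceeds the node count")
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    rng = np.random.default_rng(rng_seed)
    seed_set = set(seed_genes)
    hop1: set[str] = set()
    for g in seed_genes:
        hop1.update(network.graph.neighbors(g))
    hop1 -= seed_set
    hop2: set[str] = set()
    for g in hop1:
        hop2.update(network.graph.neighbors(g))
    hop2 -= seed_set | hop1
    pool_h1, pool_h2 = sorted(hop1), sorted(hop2)
    outside = sorted(set(nodes) - seed_set - hop1 - hop2)
    sets: dict[str, list[str]] = {}
    enriched_names = []
    for i in range(n_sets):
        name = f"PW{i:04d}"
        size = int(rng.integers(lo, min(hi, len(nodes)) + 1))
        if i < n_enriched:
            members = list(seed_genes)
            n_in = max(math.ceil(0.8 * size), len(members))
            for pool in (pool_h1, pool_h2):
                need = n_in - len(members)
                if need <= 0:
                    break
                pick = rng.choice(pool, size=min(need, len(pool)),
                                  replace=False).tolist()
                members.extend(pick)
            need_out = size - len(members)
            if need_out > 0 and outside:
                members.extend(rng.choice(
                    outside, size=min(need_out, len(outside)),
                    replace=False).tolist())
            members = sorted(set(members))
            enriched_names.append(name)
        else:
            members = sorted(rng.choice(nodes, size=size, replace=False).tolist())
        sets[name] = members
    db = PathwayDB(sets, {n: ("planted" if n in enriched_names else "random")
                          for n in sets})
    return db
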