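import numpy as np
import pandas as pd
import pytest

from budnet import (CountMatrix, PPINetwork, SampleAnnotation, normalize,
                    simulate_counts, size_factors)


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated cohort shared by read-only tests (12 high vs 3 low)."""
    cm, ann, truth = simulate_counts(n_genes=300, rng_seed=11)
    return cm, ann, truth


@pytest.fixture(scope="session")
def sim_small_norm(sim_small):
    cm, ann, _ = sim_small
    sf = size_factors(cm)
    return normalize(cm, sf), ann


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        row_ids=["g1", "g2", "g3"],
        gene_symbols=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[2, 4], [8, 16], [0, 0]]),
        level="gene",
    )


@pytest.fixture
def path_network():
    """Unweighted 3-node path 1-2-3 (unit edge weights)."""
    return PPINetwork.from_edges([("1", "2", 1.0), ("2", "3", 1.0)])


@pytest.fixture
def annotation_12v3():
    ids = [f"H{i:02d}" for i in range(1, 13)] + ["L01", "L02", "L03"]
    lv = ["high"] * 12 + ["low"] * 3
    return SampleAnnotation(pd.DataFrame({
        "sample_id": ids,
        "tb_level": lv,
        "class_label": [1.0] * 12 + [0.0] * 3,
    }))


def random_network(rng: np.random.Generator, n: int = 40,
                   p: float = 0.15) -> PPINetwork:
    """Random connected weighted graph for property tests."""
    import networkx as nx
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if nx.is_connected(g):
            break
    edges = [(f"n{a}", f"n{b}", float(rng.uniform(0.41, 1.0)))
             for a, b in g.edges]
    return PPINetwork.from_edges(edges)
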