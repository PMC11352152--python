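import numpy as np
import pandas as pd
import pytest

from budnet import (PPINetwork, SeedSet, build_kernel_system, build_seed_set,
                    diffuse, percentile_cutoff, simulate_network)
from conftest import random_network


def _seed(matched):
    return SeedSet(genes=list(matched), matched=list(matched), unmatched=[])


class TestBuildSeedSet:
    def test_intersection(self, path_network):
        ss = build_seed_set(["A", "B", "C"], ["B", "C", "D"], path_network)
        assert ss.genes == ["B", "C"]

    def test_empty_intersection_errors(self, path_network):
        with pytest.raises(ValueError, match="relax thresholds"):
            build_seed_set(["A"], ["B"], path_network)

    def test_unmatched_seed_warned_and_listed(self, path_network):
        with pytest.warns(UserWarning, match="absent from the network"):
            ss = build_seed_set(["1", "X"], ["1", "X"], path_network)
        assert ss.matched == ["1"] and ss.unmatched == ["X"]


class TestKernelSystem:
    def test_path_graph_kernel_matches_hand_inversion(self, path_network):
        system = build_kernel_system(path_network, alpha=1.0)
        K = np.linalg.inv(system.matrix.toarray())
        expected = np.array([[5, 2, 1], [2, 4, 2], [1, 2, 5]]) / 8.0
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_alpha_zero_gives_identity(self, path_network):
        system = build_kernel_system(path_network, alpha=0.0)
        np.testing.assert_allclose(system.matrix.toarray(), np.eye(3))

    def test_rows_sum_to_one(self):
        net = random_network(np.random.default_rng(1), n=30)
        for alpha in (0.5, 1.0, 7.0):
            system = build_kernel_system(net, alpha=alpha)
            ones = np.ones(len(system.nodes))
            np.testing.assert_allclose(system.matrix @ ones, ones, atol=1e-12)

    def test_negative_alpha_rejected(self, path_network):
        with pytest.raises(ValueError):
            build_kernel_system(path_network, alpha=-0.1)


class TestDiffuse:
    def test_path_graph_hand_scores(self, path_network):
        result = diffuse(path_network, _seed(["1"]), alpha=1.0)
        lut = result.set_index("node")["score"]
        np.testing.assert_allclose([lut["1"], lut["2"], lut["3"]],
                                   [0.625, 0.25, 0.125], atol=1e-10)
        assert result["rank"].tolist() == [1, 2, 3]

    def test_alpha_zero_returns_indicator(self, path_network):
        result = diffuse(path_network, _seed(["2"]), alpha=0.0)
        lut = result.set_index("node")["score"]
        assert lut["2"] == pytest.approx(1.0)
        assert lut["1"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_seeds_give_symmetric_scores(self, path_network):
        result = diffuse(path_network, _seed(["1", "3"]), alpha=1.0)
        lut = result.set_index("node")["score"]
        assert lut["1"] == pytest.approx(lut["3"], abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
    def test_conservation_and_nonnegativity(self, alpha):
        rng = np.random.default_rng(42)
        for rep in range(5):
            net = random_network(rng, n=50)
            seeds = _seed(list(np.random.default_rng(rep).choice(
                net.node_ids, size=4, replace=False)))
            result = diffuse(net, seeds, alpha=alpha)
            assert result["score"].sum() == pytest.approx(4.0, abs=1e-6)
            assert (result["score"] >= -1e-12).all()

    def test_dense_inverse_oracle(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, n=200, p=0.04)
        seeds = _seed(net.node_ids[:5])
        result = diffuse(net, seeds, alpha=1.3)
        system = build_kernel_system(net, alpha=1.3)
        y = np.isin(system.nodes, seeds.matched).astype(float)
        dense = np.linalg.inv(system.matrix.toarray()) @ y
        lut = result.set_index("node")["score"]
        np.testing.assert_allclose([lut[n] for n in system.nodes], dense,
                                   atol=1e-8)

    def test_seedless_component_scores_exactly_zero(self):
        net = PPINetwork.from_edges([("a", "b", 0.9), ("b", "c", 0.8),
                                     ("x", "y", 0.7)])
        result = diffuse(net, _seed(["a"]), alpha=1.0)
        lut = result.set_index("node")["score"]
        assert lut["x"] == 0.0 and lut["y"] == 0.0

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
    def test_locality_on_planted_communities(self, alpha):
        hits = 0
        for rep in range(20):
            net = simulate_network(
                60, model="stochastic_block",
                params={"sizes": [30, 30], "p": [[0.3, 0.01], [0.01, 0.3]]},
                rng_seed=900 + rep)
            block0 = [n for n in net.node_ids if int(n[1:]) < 30]
            block1 = [n for n in net.node_ids if int(n[1:]) >= 30]
            seeds = _seed(sorted(block0)[:3])
            result = diffuse(net, seeds, alpha=alpha)
            lut = result.set_index("node")["score"]
            inside = np.mean([lut[n] for n in block0])
            outside = np.mean([lut[n] for n in block1])
            hits += inside > outside
        assert hits == 20

    def test_scores_flatten_as_alpha_grows(self):
        net = random_network(np.random.default_rng(3), n=40)
        seeds = _seed(net.node_ids[:3])
        variances = [diffuse(net, seeds, alpha=a)["score"].var()
                     for a in (0.1, 1.0, 10.0, 100.0)]
        assert all(np.diff(variances) < 0)

    def test_no_matched_seeds_rejected(self, path_network):
        with pytest.raises(ValueError, match="matched"):
            diffuse(path_network, SeedSet(["Z"], [], ["Z"]), alpha=1.0)


class TestPercentileCutoff:
    def _result(self, n, n_seeds=7):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.uniform(size=n))[::-1]
        out = pd.DataFrame({
            "node": [f"n{i:06d}" for i in range(n)],
            "score": scores,
            "is_seed": [i < n_seeds for i in range(n)],
        })
        out["rank"] = np.arange(1, n + 1)
        return out

    def test_study_scale_quota_is_191(self):
        # ceil(0.01 * 19038) = 191 non-seed candidates at the 99th percentile
        result = self._result(19038)
        assert len(percentile_cutoff(result, percentile=99.0)) == 191

    def test_small_network_quotas(self):
        assert len(percentile_cutoff(self._result(500), 99.0)) == 5
        assert len(percentile_cutoff(self._result(100), 99.0)) == 1

    def test_seed_inclusion_switch(self):
        result = self._result(100, n_seeds=7)
        with_seeds = percentile_cutoff(result, 99.0, exclude_seeds=False)
        assert with_seeds == ["n000000"]
        without = percentile_cutoff(result, 99.0, exclude_seeds=True)
        assert without == ["n000007"]

    def test_quota_exceeding_nonseeds_warns(self):
        result = self._result(20, n_seeds=19)
        with pytest.warns(UserWarning, match="quota"):
            got = percentile_cutoff(result, percentile=50.0)
        assert got == ["n000019"]

    def test_percentile_domain(self):
        with pytest.raises(ValueError):
            percentile_cutoff(self._result(10), percentile=0.0)
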