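"""Module detection: TOM, hierarchical clustering, cohesiveness, Jaccard."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import heartnet as hn
from heartnet.modules import cohesiveness, overlap_score
from tests.conftest import best_match_jaccard


def _net(w, beta=6, tau=0.0, nodes=None):
    n = w.shape[0]
    nodes = nodes or tuple(f"g{i}" for i in range(n))
    return hn.WeightedNetwork(nodes=tuple(nodes), weights=w, beta=beta, tau=tau)


def _expr(X, genes=None):
    cols = [f"s{i}" for i in range(X.shape[1])]
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    values = pd.DataFrame(X, index=genes, columns=cols)
    meta = pd.DataFrame(
        {"group": ["A"] * X.shape[1], "replicate": range(1, X.shape[1] + 1)}, index=cols
    )
    return hn.ExpressionMatrix(values, meta)


class TestTopologicalOverlap:
    def test_triangle_hand_computation(self):
        w = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        tom = hn.topological_overlap(_net(w))
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        off = tom.to_numpy()[np.triu_indices(3, 1)]
        assert np.allclose(off, 0.5)

    def test_isolated_pair_with_unit_weight(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
        tom = hn.topological_overlap(_net(w))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        tom = hn.topological_overlap(_net(w)).to_numpy()
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        tom = hn.topological_overlap(_net(w)).to_numpy()
        k = w.sum(axis=1)
        for i in range(n):
            for j in range(i + 1, n):
                shared = sum(w[i, u] * w[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + w[i, j]) / (min(k[i], k[j]) + 1 - w[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)


class TestModuleEigengene:
    def test_identical_rows_explain_everything(self):
        x = np.tile(np.arange(8.0), (4, 1)) + np.random.default_rng(0).normal(0, 1e-9, (4, 8))
        eig, ve = hn.module_eigengene(_expr(x), [f"g{i}" for i in range(4)])
        assert ve == pytest.approx(1.0, abs=1e-6)

    def test_sign_oriented_to_mean_profile(self):
        rng = np.random.default_rng(1)
        x = np.tile(rng.normal(0, 1, 10), (5, 1)) + rng.normal(0, 0.1, (5, 10))
        eig, _ = hn.module_eigengene(_expr(x), [f"g{i}" for i in range(5)])
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        assert np.corrcoef(eig, z.mean(axis=0))[0, 1] >= 0

    def test_recovers_latent_trajectory_of_clean_module(self):
        cfg = hn.SimulationConfig(
            n_genes=30, n_modules=1, module_sizes=(30,), de_fraction=0.0,
            within_module_correlation=1 - 1e-9, n_planted_hubs=0, seed=3,
        )
        expr, truth = hn.simulate_timecourse(cfg)
        eig, ve = hn.module_eigengene(expr, truth.module_members(1))
        r = np.corrcoef(eig, truth.latent_trajectories[1])[0, 1]
        assert abs(r) >= 0.999

    def test_constant_submatrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hn.module_eigengene(_expr(np.ones((3, 6))), ["g0", "g1", "g2"])


class TestHierarchicalDetection:
    @staticmethod
    def _block_tom(sizes, within=0.9, between=0.05):
        n = sum(sizes)
        tom = np.full((n, n), between)
        start = 0
        for s in sizes:
            tom[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(tom, index=genes, columns=genes)

    def test_two_perfect_blocks_recovered(self):
        tom = self._block_tom([6, 6])
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(0, 1, (12, 8)))
        ms = hn.detect_modules_hierarchical(tom, expr, min_size=3, merge_threshold=1.1)
        assert len(ms) == 2
        got = {frozenset(m.genes) for m in ms}
        assert got == {frozenset(f"g{i}" for i in range(6)),
                       frozenset(f"g{i}" for i in range(6, 12))}

    def test_ids_ordered_by_decreasing_size(self):
        tom = self._block_tom([8, 4])
        expr = _expr(np.random.default_rng(1).normal(0, 1, (12, 8)))
        ms = hn.detect_modules_hierarchical(tom, expr, min_size=3, merge_threshold=1.1)
        assert [m.id for m in ms] == ["1A", "2A"]
        assert len(ms.modules[0]) == 8

    def test_small_clusters_go_unassigned(self):
        tom = self._block_tom([6, 2])
        expr = _expr(np.random.default_rng(2).normal(0, 1, (8, 8)))
        ms = hn.detect_modules_hierarchical(tom, expr, min_size=3, merge_threshold=1.1)
        assert len(ms) == 1
        assert set(ms.unassigned) == {"g6", "g7"}

    def test_partition_consistency(self, default_chain):
        net_t = default_chain["net_t"]
        tom = hn.topological_overlap(net_t)
        expr = default_chain["expr"].subset_genes(list(net_t.nodes))
        ms = hn.detect_modules_hierarchical(tom, expr)
        all_assigned = [g for m in ms for g in m.genes]
        assert len(all_assigned) == len(set(all_assigned))  # disjoint
        assert set(all_assigned) | set(ms.unassigned) == set(net_t.nodes)

    def test_merge_off_limit_keeps_clusters_apart(self):
        # two blocks whose expression profiles are nearly identical would
        # merge at any reasonable threshold, but not with threshold > 1
        rng = np.random.default_rng(3)
        shared = rng.normal(0, 1, 8)
        X = np.tile(shared, (12, 1)) + rng.normal(0, 0.05, (12, 8))
        tom = self._block_tom([6, 6])
        ms_off = hn.detect_modules_hierarchical(tom, _expr(X), min_size=3, merge_threshold=1.01)
        ms_on = hn.detect_modules_hierarchical(tom, _expr(X), min_size=3, merge_threshold=0.75)
        assert len(ms_off) == 2
        assert len(ms_on) == 1

    def test_min_size_validation(self):
        tom = self._block_tom([6])
        with pytest.raises(ValueError):
            hn.detect_modules_hierarchical(tom, _expr(np.random.default_rng(0).normal(size=(6, 8))), min_size=1)

    def test_planted_modules_recovered(self, default_chain):
        """On the default fixture the hierarchical catalogue matches the
        planted modules at high Jaccard."""
        net_t = default_chain["net_t"]
        tom = hn.topological_overlap(net_t)
        expr = default_chain["expr"].subset_genes(list(net_t.nodes))
        ms = hn.detect_modules_hierarchical(tom, expr)
        j = best_match_jaccard(default_chain["truth"], ms, net_t.nodes)
        assert j >= 0.8


class TestClusterone:
    def test_cohesiveness_formula(self):
        assert cohesiveness(6.0, 2.0, 4, 0.0) == pytest.approx(0.75)
        assert cohesiveness(6.0, 2.0, 4, 2.0) == pytest.approx(6.0 / 16.0)

    def test_two_cliques_with_weak_bridge_separate(self):
        n = 12
        w = np.zeros((n, n))
        for block in (range(6), range(6, 12)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        w[0, 6] = w[6, 0] = 0.1
        ms = hn.detect_modules_clusterone(
            _net(w, tau=0.05), penalty=0.0, min_size=3, min_density=0.5,
        )
        got = {frozenset(m.genes) for m in ms}
        assert got == {frozenset(f"g{i}" for i in range(6)),
                       frozenset(f"g{i}" for i in range(6, 12))}

    def test_isolated_clique_is_fixed_point(self):
        n = 5
        w = np.ones((n, n)) - np.eye(n)
        ms = hn.detect_modules_clusterone(_net(w, tau=0.5), min_size=3)
        assert len(ms) == 1
        assert set(ms.modules[0].genes) == {f"g{i}" for i in range(n)}

    def test_growth_never_decreases_cohesiveness(self, default_chain):
        ms = hn.detect_modules_clusterone(default_chain["net_t"])
        logs = ms.params["growth_logs"]
        assert logs, "no growth happened"
        for log in logs:
            assert np.all(np.diff(log) >= -1e-12)

    def test_overlap_score(self):
        a = frozenset(range(10))
        b = frozenset(range(5, 15))
        assert overlap_score(a, b) == pytest.approx(25 / 100)

    def test_requires_thresholded_network(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="tau"):
            hn.detect_modules_clusterone(_net(w, tau=0.0))

    def test_empty_edge_list_warns(self):
        w = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="empty"):
            ms = hn.detect_modules_clusterone(_net(w, tau=0.5))
        assert len(ms) == 0

    def test_planted_modules_recovered(self, default_chain):
        ms = hn.detect_modules_clusterone(default_chain["net_t"])
        j = best_match_jaccard(default_chain["truth"], ms, default_chain["net_t"].nodes)
        assert j >= 0.8
        assert all(m.id.endswith("B") for m in ms)


class TestJaccardComparison:
    @staticmethod
    def _ms(method, suffix, gene_sets):
        return hn.ModuleSet(
            method=method,
            modules=[
                hn.Module(id=f"{i}{suffix}", genes=tuple(gs))
                for i, gs in enumerate(gene_sets, start=1)
            ],
        )

    def test_identical_and_disjoint_limits(self):
        a = self._ms("hierarchical-TOM", "A", [[f"g{i}" for i in range(10)]])
        b = self._ms("cohesiveness", "B", [[f"g{i}" for i in range(10)],
                                            [f"x{i}" for i in range(5)]])
        cmp_ = hn.compare_modules_jaccard(a, b)
        assert cmp_.matrix.loc["1A", "1B"] == pytest.approx(1.0)
        assert cmp_.matrix.loc["1A", "2B"] == pytest.approx(0.0)
        assert cmp_.best_pair == ("1A", "1B")

    def test_partial_overlap_arithmetic(self):
        a = self._ms("hierarchical-TOM", "A", [[f"g{i}" for i in range(10)]])
        b = self._ms("cohesiveness", "B", [[f"g{i}" for i in range(5, 15)]])
        cmp_ = hn.compare_modules_jaccard(a, b)
        assert cmp_.matrix.loc["1A", "1B"] == pytest.approx(5 / 15)

    def test_symmetry(self, default_chain):
        net_t = default_chain["net_t"]
        tom = hn.topological_overlap(net_t)
        expr = default_chain["expr"].subset_genes(list(net_t.nodes))
        mh = hn.detect_modules_hierarchical(tom, expr)
        mc = hn.detect_modules_clusterone(net_t)
        ab = hn.compare_modules_jaccard(mh, mc).matrix
        ba = hn.compare_modules_jaccard(mc, mh).matrix
        assert np.allclose(ab.to_numpy(), ba.to_numpy().T)

    def test_empty_input_rejected(self):
        a = self._ms("hierarchical-TOM", "A", [["g1", "g2"]])
        empty = hn.ModuleSet(method="cohesiveness", modules=[])
        with pytest.raises(ValueError):
            hn.compare_modules_jaccard(a, empty)
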