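"""Module discovery: F score, cliques, greedy expansion, permutation null."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hallmarkmex.datatypes import GeneAnnotation, GeneRecord
from hallmarkmex.modules import (
    candidate_pool,
    discover_modules,
    greedy_expand,
    maximal_cliques,
    merge_meta_genes,
    mex_score,
    module_size_meta,
    permutation_pvalues,
    permutation_test,
    rewire_profile,
    select_modules,
)
from hallmarkmex.network import MexNetwork
from hallmarkmex._rewire import rewire_binary_matrix, _swap_kernel_py
from tests.conftest import brute_force_maximal_cliques, f_score_oracle, make_profile


class TestMexScore:
    def test_perfect_exclusivity_equals_coverage(self):
        mat = np.zeros((10, 2), dtype=int)
        mat[:3, 0] = 1
        mat[3:7, 1] = 1
        prof = make_profile(mat)
        assert mex_score(["G0", "G1"], prof) == pytest.approx(7.0)

    def test_fully_redundant_pair(self):
        mat = np.zeros((10, 2), dtype=int)
        mat[:5, 0] = 1
        mat[:5, 1] = 1
        prof = make_profile(mat)
        assert mex_score(["G0", "G1"], prof) == pytest.approx(5 / 6)

    def test_partial_overlap(self):
        # g1 on samples 0-4, g2 on 3-7: union 8, total 10 -> F = 8/3
        mat = np.zeros((10, 2), dtype=int)
        mat[0:5, 0] = 1
        mat[3:8, 1] = 1
        prof = make_profile(mat)
        assert mex_score(["G0", "G1"], prof) == pytest.approx(8 / 3)

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_s, n_g = int(rng.integers(5, 30)), int(rng.integers(2, 8))
            mat = (rng.random((n_s, n_g)) < 0.3).astype(int)
            prof = make_profile(mat)
            k = int(rng.integers(1, n_g + 1))
            idx = sorted(rng.choice(n_g, size=k, replace=False))
            members = [f"G{i}" for i in idx]
            assert mex_score(members, prof) == f_score_oracle(mat, idx)

    def test_missing_member_errors(self):
        prof = make_profile(np.ones((3, 1), dtype=int))
        with pytest.raises(KeyError):
            mex_score(["G0", "nope"], prof)


class TestMaximalCliques:
    def net(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return MexNetwork("Inducing Angiogenesis", g)

    def test_triangle(self):
        assert maximal_cliques(self.net([("a", "b"), ("b", "c"), ("a", "c")])) == [
            frozenset({"a", "b", "c"})
        ]

    def test_path(self):
        out = set(maximal_cliques(self.net([("a", "b"), ("b", "c")])))
        assert out == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_singleton_node(self):
        out = set(maximal_cliques(self.net([("a", "b")], nodes=["z"])))
        assert frozenset({"z"}) in out

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
            out = set(maximal_cliques(MexNetwork("x", g)))
            assert out == set(brute_force_maximal_cliques(g))


class TestCandidatePool:
    def pool_profile(self):
        # members G0,G1 disjoint; G2 disjoint candidate; G3 overlaps G0 heavily;
        # G4 is an off-hallmark PCG
        mat = np.zeros((60, 5), dtype=int)
        mat[0:20, 0] = 1
        mat[20:40, 1] = 1
        mat[40:55, 2] = 1
        mat[0:15, 3] = 1  # overlap 15 with G0, unique 0 vs 5
        mat[55:60, 4] = 1
        return make_profile(mat)

    def test_criteria(self, hallmark_all):
        prof = self.pool_profile()
        hs = hallmark_all(["G0", "G1", "G2", "G3"])
        pool = candidate_pool(["G0", "G1"], prof, hs)
        assert "G2" in pool  # disjoint, significant
        assert "G3" not in pool  # fails pairwise-overlap criterion (iv)
        assert "G4" not in pool  # off-hallmark PCG, criterion (ii)

    def test_lncrna_exempt_from_hallmark(self, hallmark_all):
        mat = np.zeros((60, 3), dtype=int)
        mat[0:20, 0] = 1
        mat[20:40, 1] = 1
        mat[40:55, 2] = 1
        prof = make_profile(mat, gene_classes=["pcg", "pcg", "lncrna"])
        hs = hallmark_all(["G0", "G1"])  # G2 not hallmark-associated, but lncRNA
        assert "G2" in candidate_pool(["G0", "G1"], prof, hs)


class TestGreedyExpand:
    def test_fixpoint_when_no_candidates(self, hallmark_all):
        mat = np.zeros((30, 3), dtype=int)
        mat[0:8, 0] = 1
        mat[8:16, 1] = 1
        mat[16:24, 2] = 1
        prof = make_profile(mat)
        hs = hallmark_all(prof.genes)
        mod = greedy_expand(["G0", "G1", "G2"], prof, hs)
        assert mod.members == frozenset({"G0", "G1", "G2"})
        assert mod.f_score == pytest.approx(24.0)

    def test_expands_and_f_increases(self, hallmark_all):
        mat = np.zeros((60, 3), dtype=int)
        mat[0:15, 0] = 1
        mat[15:30, 1] = 1
        mat[30:45, 2] = 1
        prof = make_profile(mat)
        hs = hallmark_all(prof.genes)
        seed_f = mex_score(["G0", "G1"], prof)
        mod = greedy_expand(["G0", "G1"], prof, hs)
        assert mod.members == frozenset({"G0", "G1", "G2"})
        assert mod.f_score > seed_f
        assert mod.coverage == 45

    def test_never_beats_exhaustive_optimum(self, hallmark_all):
        rng = np.random.default_rng(8)
        for _ in range(5):
            mat = (rng.random((40, 8)) < 0.15).astype(int)
            keep = mat.sum(axis=0) > 0
            mat = mat[:, keep]
            prof = make_profile(mat)
            hs = hallmark_all(prof.genes)
            genes = prof.genes
            mod = greedy_expand(genes[:2], prof, hs)
            # exhaustive best F over all supersets of the seed
            best = 0.0
            rest = [g for g in genes if g not in genes[:2]]
            for r in range(len(rest) + 1):
                for extra in itertools.combinations(rest, r):
                    best = max(best, mex_score(list(genes[:2]) + list(extra), prof))
            assert mod.f_score <= best + 1e-12


class TestRewiring:
    def test_margins_preserved_every_draw(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            mat = (rng.random((15, 10)) < 0.3).astype(np.int8)
            out = rewire_binary_matrix(mat, rng)
            assert np.array_equal(out.sum(axis=0), mat.sum(axis=0))
            assert np.array_equal(out.sum(axis=1), mat.sum(axis=1))
            assert set(np.unique(out)) <= {0, 1}

    def test_checkerboard_two_states(self):
        start = np.array([[1, 0], [0, 1]], dtype=np.int8)
        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(50):
            out = rewire_binary_matrix(start, rng, swap_factor=5)
            seen.add(tuple(out.ravel()))
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_python_and_default_kernels_agree(self):
        rng_a = np.random.default_rng(77)
        rng_b = np.random.default_rng(77)
        mat = (np.random.default_rng(0).random((20, 12)) < 0.25).astype(np.int8)
        out_a = rewire_binary_matrix(mat, rng_a)
        out_b = rewire_binary_matrix(mat, rng_b, use_python_kernel=True)
        assert np.array_equal(out_a, out_b)

    def test_rewire_profile_wrapper(self):
        prof = make_profile((np.random.default_rng(2).random((20, 6)) < 0.3).astype(int))
        out = rewire_profile(prof, 123)
        assert list(out.matrix.columns) == prof.genes
        assert (out.matrix.sum(axis=0) == prof.matrix.sum(axis=0)).all()


class TestPermutationTest:
    def planted_profile(self):
        mat = np.zeros((200, 3), dtype=int)
        mat[0:40, 0] = 1
        mat[40:80, 1] = 1
        mat[80:120, 2] = 1
        rng = np.random.default_rng(6)
        noise = (rng.random((200, 3)) < 0.02).astype(int)
        return make_profile(np.maximum(mat, noise))

    def test_planted_module_p_zero(self, hallmark_all):
        prof = self.planted_profile()
        mod = greedy_expand(prof.genes, prof, hallmark_all(prof.genes))
        p = permutation_test(mod, prof, n_perm=200, rng=42)
        assert p == 0.0

    def test_single_gene_module_p_zero(self):
        prof = make_profile((np.random.default_rng(1).random((30, 4)) < 0.3).astype(int))
        p = permutation_pvalues(prof, [frozenset({"G0"})], 100, 7)[0]
        # gene-wise margins are preserved, so F never exceeds the observed value
        assert p == 0.0

    def test_bit_reproducible(self):
        prof = self.planted_profile()
        ms = [frozenset({"G0", "G1"}), frozenset({"G0", "G2"})]
        p1 = permutation_pvalues(prof, ms, 150, np.random.default_rng(9))
        p2 = permutation_pvalues(prof, ms, 150, np.random.default_rng(9))
        assert np.array_equal(p1, p2)

    def test_n_perm_validation(self):
        prof = self.planted_profile()
        with pytest.raises(ValueError):
            permutation_pvalues(prof, [frozenset({"G0"})], 0, 1)


class TestSelectModules:
    def mod(self, members, p, hallmark="Inducing Angiogenesis"):
        from hallmarkmex.datatypes import Module

        return Module(
            members=frozenset(members),
            hallmark=hallmark,
            f_score=1.0,
            coverage=1,
            member_gammas={m: 1 for m in members},
            p_empirical=p,
        )

    def test_single_significant_kept(self):
        mods = [self.mod([f"a{i}", f"b{i}"], 0.5) for i in range(9)]
        mods.append(self.mod(["x", "y"], 0.001))
        kept = select_modules(mods)
        assert len(kept) == 1
        assert kept[0].p_adjusted == pytest.approx(0.01)

    def test_all_zero_all_kept(self):
        mods = [self.mod([f"a{i}", "b"], 0.0) for i in range(5)]
        assert len(select_modules(mods)) == 5

    def test_bonferroni_kills_marginal(self):
        mods = [self.mod([f"a{i}", f"b{i}"], 0.001) for i in range(100)]
        assert select_modules(mods) == []
        assert mods[0].p_adjusted == pytest.approx(0.1)

    def test_duplicates_collapsed_before_adjustment(self):
        mods = [self.mod(["x", "y"], 0.01) for _ in range(10)]
        kept = select_modules(mods)
        assert len(kept) == 1
        assert kept[0].p_adjusted == pytest.approx(0.01)  # m = 1 after dedup


class TestMetaGenes:
    def annot(self, bands):
        return GeneAnnotation(
            [
                GeneRecord(g, "pcg", "chr1", 100 * i, 100 * i + 50, "+", band)
                for i, (g, band) in enumerate(bands.items())
            ]
        )

    def net(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes, gene_class="pcg")
        for u, v in edges:
            g.add_edge(u, v)
        for n in g.nodes:
            g.nodes[n].setdefault("gene_class", "pcg")
        return MexNetwork("Inducing Angiogenesis", g)

    def test_same_band_same_neighbors_merged(self):
        net = self.net([("a", "x"), ("b", "x")])
        annot = self.annot({"a": "1q1", "b": "1q1", "x": "2p1"})
        merged, metas, mapping = merge_meta_genes(net, annot)
        assert merged.graph.number_of_nodes() == 2
        assert len(metas) == 1
        assert metas[0].members == frozenset({"a", "b"})
        assert metas[0].meta_id == "1q1|a"  # lexicographically smallest representative

    def test_different_neighbors_not_merged(self):
        net = self.net([("a", "x"), ("b", "y")])
        annot = self.annot({"a": "1q1", "b": "1q1", "x": "2p1", "y": "2p1"})
        merged, metas, _ = merge_meta_genes(net, annot)
        assert merged.graph.number_of_nodes() == 4
        assert metas == []

    def test_chain_of_three_transitive(self):
        # a-b-c all same band; pairwise neighbor sets (excluding each other) agree
        net = self.net([("a", "b"), ("b", "c"), ("a", "c"), ("a", "x"), ("b", "x"), ("c", "x")])
        annot = self.annot({"a": "1q1", "b": "1q1", "c": "1q1", "x": "2p1"})
        merged, metas, mapping = merge_meta_genes(net, annot)
        assert len(metas) == 1
        assert metas[0].members == frozenset({"a", "b", "c"})
        assert mapping["c"] == "a"

    def test_module_size_in_meta_units(self):
        from hallmarkmex.datatypes import Module

        mod = Module(
            members=frozenset({"a", "b", "x"}),
            hallmark="Inducing Angiogenesis",
            f_score=1.0,
            coverage=1,
            member_gammas={},
        )
        assert module_size_meta(mod, {"a": "a", "b": "a", "x": "x"}) == 2


class TestDiscoverModules:
    def test_recovers_planted_module(self, hallmark_all):
        mat = np.zeros((100, 5), dtype=int)
        mat[0:20, 0] = 1
        mat[20:40, 1] = 1
        mat[40:60, 2] = 1
        rng = np.random.default_rng(3)
        mat[:, 3] = rng.random(100) < 0.05
        mat[:, 4] = rng.random(100) < 0.05
        prof = make_profile(mat)
        selected, all_mods, networks = discover_modules(
            prof, [hallmark_all(prof.genes)], n_perm=200, rng=11
        )
        assert any(frozenset({"G0", "G1", "G2"}) <= m.members for m in selected)
        assert all(m.p_adjusted is not None for m in selected)
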