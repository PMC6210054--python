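"""Wang semantic similarity, hallmark term expansion and enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hallmarkmex.datatypes import HallmarkGeneSet, HallmarkTermSet
from hallmarkmex.ontology import (
    GoDag,
    bma_similarity,
    derive_threshold,
    enrichment_check,
    expand_terms,
    hallmark_genes,
    hypergeom_enrichment,
    set_similarity,
    term_similarity,
)


class TestTermSimilarity:
    def test_self_identity(self, toy_dag):
        for t in ["root", "a", "b", "c"]:
            assert term_similarity(t, t, toy_dag) == 1.0

    def test_disjoint_components_zero(self, toy_dag):
        assert term_similarity("b", "island", toy_dag) == 0.0

    def test_hand_computed_chain(self, toy_dag):
        # b: S = {b:1, a:0.8, root:0.64}, SV = 2.44
        # c: S = {c:1, root:0.8},        SV = 1.8
        # shared {root}: (0.64 + 0.8) / (2.44 + 1.8) = 1.44 / 4.24
        assert term_similarity("b", "c", toy_dag) == pytest.approx(1.44 / 4.24)

    def test_symmetry_random_dags(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            n = 8
            edges = [(f"t{i}", f"t{int(rng.integers(0, i))}") for i in range(1, n)]
            dag = GoDag(edges)
            for t1, t2 in itertools.combinations([f"t{i}" for i in range(n)], 2):
                assert term_similarity(t1, t2, dag) == pytest.approx(
                    term_similarity(t2, t1, dag)
                )

    def test_unknown_term_errors(self, toy_dag):
        with pytest.raises(KeyError):
            term_similarity("a", "nope", toy_dag)


class TestSetSimilarity:
    def test_singleton_reference_identity(self, toy_dag):
        assert set_similarity("b", ["b"], toy_dag) == 1.0

    def test_disjoint_component_zero(self, toy_dag):
        assert set_similarity("island", ["a", "b", "c"], toy_dag) == 0.0

    def test_match_dominates(self, toy_dag):
        # query 'a' identical to one reference term: BMA averages the perfect
        # best-match for the query row with the per-reference best matches.
        ref = ["a", "c"]
        sims = [term_similarity("a", t, toy_dag) for t in ref]
        expected = (max(sims) + sum(sims)) / (1 + len(ref))
        assert set_similarity("a", ref, toy_dag) == pytest.approx(expected)
        assert set_similarity("a", ref, toy_dag) > set_similarity("b", ref, toy_dag) / 2

    def test_empty_reference_errors(self, toy_dag):
        with pytest.raises(ValueError):
            set_similarity("a", [], toy_dag)


class TestDeriveThreshold:
    def test_two_term_hallmark_gives_pair_similarity(self, toy_dag):
        hset = HallmarkTermSet(
            "Resisting Cell Death", {"b", "c"}, {"b": "curated", "c": "curated"}
        )
        # leave-one-out score of b is sim(b, c) and vice versa -> min is that value
        expected = term_similarity("b", "c", toy_dag)
        assert derive_threshold([hset], toy_dag) == pytest.approx(expected)

    def test_minimum_across_hallmarks(self, toy_dag):
        near = HallmarkTermSet("Inducing Angiogenesis", {"a", "b"},
                               {"a": "curated", "b": "curated"})
        far = HallmarkTermSet("Resisting Cell Death", {"b", "c"},
                              {"b": "curated", "c": "curated"})
        expected = min(term_similarity("a", "b", toy_dag), term_similarity("b", "c", toy_dag))
        assert derive_threshold([near, far], toy_dag) == pytest.approx(expected)

    def test_single_term_hallmark_excluded(self, toy_dag):
        lone = HallmarkTermSet("Inducing Angiogenesis", {"a"}, {"a": "curated"})
        pair = HallmarkTermSet("Resisting Cell Death", {"b", "c"},
                               {"b": "curated", "c": "curated"})
        assert derive_threshold([lone, pair], toy_dag) == pytest.approx(
            term_similarity("b", "c", toy_dag)
        )
        with pytest.raises(ValueError):
            derive_threshold([lone], toy_dag)

    def test_generated_sets_match_independent_recomputation(self):
        from hallmarkmex.simulate import generate_ontology, pcg_ids

        dag, curated, _ = generate_ontology(pcg_ids(30), seed=5, n_hallmarks=4)
        observed = derive_threshold(curated, dag)
        # independent leave-one-out recomputation straight from the definition
        scores = []
        for hset in curated:
            terms = sorted(hset.terms)
            for t in terms:
                rest = [x for x in terms if x != t]
                sims = [term_similarity(t, r, dag) for r in rest]
                scores.append((max(sims) + sum(sims)) / (1 + len(rest)))
        assert observed == pytest.approx(min(scores))


class TestExpandTerms:
    def hallmark(self, terms):
        return HallmarkTermSet(
            "Tissue Invasion and Metastasis", set(terms), {t: "curated" for t in terms}
        )

    def test_identical_candidate_joins(self, toy_dag):
        out = expand_terms(["a"], [self.hallmark(["a", "b"])], toy_dag, threshold=0.5)
        assert "a" in out[0].terms

    def test_disjoint_candidate_joins_nothing(self, toy_dag):
        out = expand_terms(["island"], [self.hallmark(["a", "b"])], toy_dag, threshold=0.01)
        assert "island" not in out[0].terms

    def test_threshold_routes_candidate(self, toy_dag):
        near = self.hallmark(["a", "b"])
        far = HallmarkTermSet("Resisting Cell Death", {"c"}, {"c": "curated"})
        score_near = set_similarity("root", ["a", "b"], toy_dag)
        score_far = set_similarity("root", ["c"], toy_dag)
        thr = (score_near + score_far) / 2
        assert score_far < thr < score_near or score_near < thr < score_far
        out = expand_terms(["root"], [near, far], toy_dag, thr)
        joined = {s.hallmark for s in out if "root" in s.terms}
        expected = near.hallmark if score_near > score_far else far.hallmark
        assert joined == {expected}

    def test_monotone_in_threshold(self, toy_dag):
        cands = ["root", "c", "island"]
        hset = self.hallmark(["a", "b"])
        lo = expand_terms(cands, [hset], toy_dag, 0.0)[0].terms
        hi = expand_terms(cands, [hset], toy_dag, 0.6)[0].terms
        assert hi <= lo

    def test_extreme_thresholds(self, toy_dag):
        hset = self.hallmark(["a", "b"])
        all_in = expand_terms(["root", "c"], [hset], toy_dag, 0.0)[0]
        assert {"root", "c"} <= all_in.terms  # same component joins at threshold 0
        none_in = expand_terms(["root", "c"], [hset], toy_dag, 1.1)[0]
        assert none_in.terms == {"a", "b"}  # curated always retained


class TestHallmarkGenes:
    def test_propagation_and_membership(self, toy_dag):
        toy_dag.annotations = {"g_direct": {"a"}, "g_child": {"b"}, "g_none": set()}
        toy_dag._prop_cache = None
        hset = HallmarkTermSet("Inducing Angiogenesis", {"a"}, {"a": "curated"})
        out = hallmark_genes([hset], toy_dag)[0]
        assert "g_direct" in out.genes
        assert "g_child" in out.genes  # annotated to child b, propagates to a
        assert "g_none" not in out.genes

    def test_direct_only_mode(self, toy_dag):
        toy_dag.annotations = {"g_child": {"b"}}
        toy_dag._prop_cache = None
        hset = HallmarkTermSet("Inducing Angiogenesis", {"a"}, {"a": "curated"})
        out = hallmark_genes([hset], toy_dag, propagated=False)[0]
        assert out.genes == set()


class TestEnrichment:
    def test_closed_form_minimal_p(self):
        background = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        table = hypergeom_enrichment(pathway, {"pw": pathway}, background)
        from math import comb

        assert table.loc[0, "p"] == pytest.approx(1 / comb(100, 10))

    def test_null_pvalues_not_inflated(self):
        rng = np.random.default_rng(23)
        background = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        pvals = []
        for _ in range(1000):
            query = set(rng.choice(sorted(background), size=10, replace=False))
            table = hypergeom_enrichment(query, {"pw": pathway}, background)
            pvals.append(table.loc[0, "p"])
        # discrete p-values: check the null rejection rate is at most nominal
        assert np.mean(np.array(pvals) <= 0.05) <= 0.08
        assert 0.35 < np.mean(pvals)

    def test_empty_query(self):
        out = enrichment_check(
            HallmarkGeneSet("Inducing Angiogenesis", set()),
            {"pw": {"g1"}},
            {"g1", "g2"},
        )
        assert out.empty

    def test_no_background_overlap_skipped(self):
        background = {"g1", "g2"}
        table = hypergeom_enrichment({"g1"}, {"pw": {"x1", "x2"}}, background)
        assert table.empty
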