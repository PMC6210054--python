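"""Hallmark GO-term expansion by semantic similarity and hallmark gene sets.

Curated hallmark term sets are expanded with candidate GO terms whose
functional similarity score against the curated set reaches a
data-derived threshold (the minimum leave-one-out score of the curated
terms themselves). Similarity is Wang's graph-based measure over is_a
paths, aggregated set-wise by best-match averaging — the canonical
configuration of GOSemSim's ``mgoSim``. The measure is pluggable so
information-content variants can be swapped in.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HallmarkGeneSet, HallmarkTermSet

logger = logging.getLogger(__name__)

#: Contribution factor of an is_a edge in Wang's measure.
WANG_ISA_WEIGHT = 0.8


class GoDag:
    """A Gene Ontology DAG restricted to is_a links, plus gene annotations.

    Edges run child -> parent. Annotations map gene ids to directly
    assigned term ids; :meth:`propagated_annotations` applies the
    true-path rule (a gene annotated to a term is annotated to all its
    ancestors).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        terms: Iterable[str] | None = None,
        annotations: Mapping[str, set[str]] | None = None,
    ):
        self.graph = nx.DiGraph()
        if terms is not None:
            self.graph.add_nodes_from(terms)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO is_a graph must be acyclic")
        self.annotations: dict[str, set[str]] = {
            g: set(ts) for g, ts in (annotations or {}).items()
        }
        missing = {
            t for ts in self.annotations.values() for t in ts if t not in self.graph
        }
        if missing:
            raise ValueError(f"annotated terms missing from DAG: {sorted(missing)[:5]}")
        self._svalue_cache: dict[str, tuple[dict[str, float], float]] = {}
        self._prop_cache: dict[str, set[str]] | None = None

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (term excluded)."""
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def propagated_annotations(self) -> dict[str, set[str]]:
        """Gene -> term sets after true-path propagation to all ancestors."""
        if self._prop_cache is None:
            self._prop_cache = {
                g: set().union(ts, *(self.ancestors(t) for t in ts))
                for g, ts in self.annotations.items()
            }
        return self._prop_cache

    def annotated_genes(self, term: str, propagated: bool = True) -> set[str]:
        ann = self.propagated_annotations() if propagated else self.annotations
        return {g for g, ts in ann.items() if term in ts}

    # -- Wang semantic similarity ------------------------------------------

    def _svalues(self, term: str, w: float = WANG_ISA_WEIGHT) -> tuple[dict[str, float], float]:
        """S-values of ``term``'s ancestor DAG and their sum (semantic value).

        S(term) = 1; each ancestor's S is the best downward-path product
        of edge weights from the term.
        """
        if term in self._svalue_cache:
            return self._svalue_cache[term]
        anc = self.ancestors(term) | {term}
        sub = self.graph.subgraph(anc)
        s = {term: 1.0}
        # topological order of the child->parent subgraph puts children first
        for node in nx.topological_sort(sub):
            if node not in s:
                continue
            for parent in sub.successors(node):
                cand = w * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        sv = sum(s.values())
        self._svalue_cache[term] = (s, sv)
        return s, sv


def term_similarity(t1: str, t2: str, dag: GoDag) -> float:
    """Wang similarity of two GO terms in [0, 1]; 1 iff identical, 0 if disjoint ancestry."""
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"term {t!r} not in DAG")
    if t1 == t2:
        return 1.0
    s1, sv1 = dag._svalues(t1)
    s2, sv2 = dag._svalues(t2)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sv1 + sv2)


def bma_similarity(
    set_a: Iterable[str],
    set_b: Iterable[str],
    dag: GoDag,
    measure: Callable[[str, str, "GoDag"], float] = term_similarity,
) -> float:
    """Best-match-average similarity between two term sets."""
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("both term sets must be non-empty")
    sim = np.array([[measure(x, y, dag) for y in b] for x in a])
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(a) + len(b)))


def set_similarity(
    query: str,
    reference: Iterable[str],
    dag: GoDag,
    measure: Callable[[str, str, "GoDag"], float] = term_similarity,
) -> float:
    """Functional similarity score of one term against a reference term set (BMA)."""
    return bma_similarity([query], reference, dag, measure)


def derive_threshold(curated: list[HallmarkTermSet], dag: GoDag) -> float:
    """Minimum leave-one-out similarity of curated terms to their own hallmark set.

    For every curated term, its similarity score against the remaining
    curated terms of the same hallmark is computed; the global minimum
    is the expansion threshold. Hallmarks with fewer than two curated
    terms cannot contribute and are skipped with a warning.
    """
    scores: list[float] = []
    for hset in curated:
        terms = sorted(hset.curated_terms or hset.terms)
        if len(terms) < 2:
            logger.warning(
                "hallmark %r has <2 curated terms; excluded from threshold derivation",
                hset.hallmark,
            )
            continue
        for t in terms:
            rest = [x for x in terms if x != t]
            scores.append(set_similarity(t, rest, dag))
    if not scores:
        raise ValueError("no hallmark with >=2 curated terms; threshold undefined")
    return min(scores)


def expand_terms(
    candidates: Iterable[str],
    curated: list[HallmarkTermSet],
    dag: GoDag,
    threshold: float,
) -> list[HallmarkTermSet]:
    """Attach candidate terms to every hallmark they resemble at ``threshold``.

    A candidate joins a hallmark iff its similarity score against that
    hallmark's curated set is >= threshold (inclusive: the threshold is
    itself an observed minimum score). Curated terms are always kept; a
    term may join several hallmarks.
    """
    if not 0 <= threshold:
        raise ValueError("threshold must be nonnegative")
    out: list[HallmarkTermSet] = []
    for hset in curated:
        cur = set(hset.curated_terms or hset.terms)
        terms = set(cur)
        prov = {t: "curated" for t in cur}
        for cand in candidates:
            if cand in cur:
                continue
            if set_similarity(cand, sorted(cur), dag) >= threshold:
                terms.add(cand)
                prov[cand] = "expanded"
        out.append(HallmarkTermSet(hset.hallmark, terms, prov))
    return out


def hallmark_genes(
    termsets: list[HallmarkTermSet], dag: GoDag, *, propagated: bool = True
) -> list[HallmarkGeneSet]:
    """Genes annotated (with true-path propagation) to >=1 term of each hallmark."""
    ann = dag.propagated_annotations() if propagated else dag.annotations
    out = []
    for hset in termsets:
        genes = {g for g, ts in ann.items() if ts & hset.terms}
        out.append(HallmarkGeneSet(hset.hallmark, genes))
    return out


def hypergeom_enrichment(
    query: set[str],
    gene_sets: Mapping[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH FDR.

    Returns a table (set_name, n_set, n_overlap, p, fdr) sorted by p.
    Sets with no overlap with the background are skipped.
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for name, genes in gene_sets.items():
        in_bg = genes & background
        if not in_bg:
            continue
        k = len(query & in_bg)
        p = stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_q) if n_q else 1.0
        rows.append((name, len(in_bg), k, float(p)))
    table = pd.DataFrame(rows, columns=["set_name", "n_set", "n_overlap", "p"])
    if table.empty:
        table["fdr"] = pd.Series(dtype=float)
        return table
    table["fdr"] = stats.false_discovery_control(table["p"], method="bh")
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def enrichment_check(
    genes: HallmarkGeneSet,
    pathway_db: Mapping[str, set[str]],
    background: set[str],
    *,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Pathway over-representation of a hallmark gene set (validation step)."""
    if not genes.genes:
        return pd.DataFrame(
            columns=["set_name", "n_set", "n_overlap", "p", "fdr", "significant"]
        )
    table = hypergeom_enrichment(genes.genes & background, pathway_db, background)
    table["significant"] = table["fdr"] < alpha_fdr
    return table
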