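import numpy as np
import pandas as pd
import pytest

from hallmarkmex.datatypes import (
    BinaryAlterationProfile,
    CnaCallSet,
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    HallmarkGeneSet,
)
from hallmarkmex.ontology import GoDag


def make_profile(matrix: np.ndarray, gene_classes=None, signs=None, samples=None, genes=None):
    """Binary profile from a plain 0/1 array (helper for hand-built cases)."""
    n_s, n_g = matrix.shape
    samples = samples or [f"S{i}" for i in range(n_s)]
    genes = genes or [f"G{i}" for i in range(n_g)]
    gene_classes = gene_classes or ["pcg"] * n_g
    signs = signs or ["amp"] * n_g
    return BinaryAlterationProfile(
        pd.DataFrame(np.asarray(matrix, dtype=np.int8), index=samples, columns=genes),
        pd.Series(signs, index=genes, name="sign"),
        pd.Series(gene_classes, index=genes, name="class"),
    )


@pytest.fixture
def toy_dag():
    """root -> a -> b and root -> c, plus a disjoint island term."""
    return GoDag(
        [("a", "root"), ("b", "a"), ("c", "root")],
        terms=["root", "a", "b", "c", "island"],
    )


@pytest.fixture
def annotation_small():
    return GeneAnnotation(
        [
            GeneRecord("PCG1", "pcg", "chr1", 100, 200, "+", "1q1"),
            GeneRecord("PCG2", "pcg", "chr1", 1000, 2000, "-", "1q1"),
            GeneRecord("LNC1", "lncrna", "chr1", 150, 300, "-", "1q1"),
            GeneRecord("LNC2", "lncrna", "chr2", 100, 200, "+", "2p1"),
        ]
    )


@pytest.fixture
def hallmark_all():
    def _make(genes, hallmark="Tissue Invasion and Metastasis"):
        return HallmarkGeneSet(hallmark, set(genes))

    return _make


def brute_force_maximal_cliques(graph):
    """Exhaustive maximal-clique enumeration over all vertex subsets (oracle)."""
    import itertools

    nodes = list(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    return [c for c in cliques if not any(c < d for d in cliques)]


def f_score_oracle(matrix: np.ndarray, member_idx, alpha=1.0):
    """Set-arithmetic F oracle: explicit union / overlap computation."""
    sets = [set(np.nonzero(matrix[:, j])[0]) for j in member_idx]
    union = set().union(*sets)
    total = sum(len(s) for s in sets)
    return len(union) / (total - len(union) + alpha)
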