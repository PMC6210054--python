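"""Per-hallmark mutual-exclusivity networks.

Nodes are the hallmark's protein-coding genes plus all lncRNAs present
in the binary alteration profile; an edge connects two genes whose
alterations overlap less than expected (hypergeometric lower tail,
p < alpha) or never co-occur at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import BinaryAlterationProfile, HallmarkGeneSet


@dataclass(frozen=True)
class MexEdge:
    gene_a: str
    gene_b: str
    p_value: float
    rule: Literal["hypergeometric", "zero_overlap"]
    overlap: int

    def __post_init__(self) -> None:
        if self.rule == "zero_overlap" and self.overlap != 0:
            raise ValueError("zero_overlap rule requires overlap == 0")


@dataclass
class MexNetwork:
    """Undirected mutual-exclusivity network for one hallmark."""

    hallmark: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[MexEdge]:
        return [
            MexEdge(a, b, d["p_value"], d["rule"], d["overlap"])
            for a, b, d in self.graph.edges(data=True)
        ]


def pair_test(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Mutual-exclusivity p for two binary alteration vectors.

    Under the null that gene b's alterations fall uniformly among the N
    samples, the overlap with gene a's |a| altered samples is
    hypergeometric; the lower-tail probability P(X <= k) measures how
    surprisingly small the observed co-occurrence k is. Equivalent to a
    one-sided Fisher exact test ("less") on the 2x2 table.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("vectors must be non-empty and of equal length")
    if not a.any() or not b.any():
        raise ValueError("both genes must be altered in at least one sample")
    n = a.size
    k = int(np.sum(a & b))
    p = float(stats.hypergeom.cdf(k, n, int(b.sum()), int(a.sum())))
    return p, k


def build_network(
    profile: BinaryAlterationProfile,
    hallmark_genes: HallmarkGeneSet,
    alpha: float = 0.05,
) -> MexNetwork:
    """Mutual-exclusivity network among a hallmark's PCGs and all lncRNAs.

    Every pair (PCG-PCG, lncRNA-lncRNA, PCG-lncRNA) in the candidate
    node set is tested; an edge is added when the pair is significantly
    exclusive (p < alpha) or its co-occurrence is never observed.
    """
    pcgs = [g for g in profile.pcg_genes() if g in hallmark_genes.genes]
    lncs = profile.lncrna_genes()
    nodes = pcgs + [g for g in lncs if g not in set(pcgs)]

    g = nx.Graph(hallmark=hallmark_genes.hallmark)
    for node in nodes:
        g.add_node(node, gene_class=str(profile.gene_class[node]))
    if len(nodes) >= 2:
        mat = profile.matrix[nodes].to_numpy(dtype=bool)
        n = mat.shape[0]
        gamma = mat.sum(axis=0)
        overlap = (mat.T.astype(np.int64)) @ mat.astype(np.int64)
        iu, ju = np.triu_indices(len(nodes), k=1)
        k = overlap[iu, ju]
        p = stats.hypergeom.cdf(k, n, gamma[ju], gamma[iu])
        for idx in range(iu.size):
            a, b = nodes[iu[idx]], nodes[ju[idx]]
            pv, kk = float(p[idx]), int(k[idx])
            if pv < alpha:
                g.add_edge(a, b, p_value=pv, rule="hypergeometric", overlap=kk)
            elif kk == 0:
                g.add_edge(a, b, p_value=pv, rule="zero_overlap", overlap=0)
    return MexNetwork(hallmark_genes.hallmark, g)
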