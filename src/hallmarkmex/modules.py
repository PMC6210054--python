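"""Mutually exclusive module discovery.

Maximal cliques of the per-hallmark exclusivity network seed a greedy
expansion that maximises the exclusivity objective

    F = Gamma(M) / (sum_i Gamma(g_i) - Gamma(M) + alpha),

where Gamma(g_i) is the number of samples altered in member g_i and
Gamma(M) the number altered in at least one member; alpha (default 1)
keeps the denominator positive. Perfect exclusivity gives F equal to
the coverage; overlap inflates the denominator and pulls F down.
Significance is assessed against a margin-preserving permutation null
(checkerboard rewiring of the binary profile), followed by Bonferroni
family-wise correction across the modules tested in a run.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._rewire import rewire_binary_matrix
from .datatypes import BinaryAlterationProfile, GeneAnnotation, HallmarkGeneSet, MetaGene, Module
from .network import MexNetwork, build_network, pair_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scoring

def mex_score(
    members: Iterable[str],
    profile: BinaryAlterationProfile,
    alpha_const: float = 1.0,
) -> float:
    """Exclusivity score F of a gene set on a binary profile."""
    members = list(members)
    if not members:
        raise ValueError("members must be non-empty")
    missing = [g for g in members if g not in profile.matrix.columns]
    if missing:
        raise KeyError(f"members absent from profile: {missing}")
    sub = profile.matrix[members].to_numpy(dtype=bool)
    coverage = int(np.any(sub, axis=1).sum())
    total = int(sub.sum())
    return coverage / (total - coverage + alpha_const)


def _score_indexed(X: np.ndarray, idx: np.ndarray, alpha_const: float) -> tuple[float, int, int]:
    sub = X[:, idx]
    coverage = int(np.logical_or.reduce(sub, axis=1).sum()) if idx.size else 0
    total = int(sub.sum())
    return coverage / (total - coverage + alpha_const), coverage, total


# ---------------------------------------------------------------------------
# seeds

def maximal_cliques(network: MexNetwork) -> list[frozenset[str]]:
    """All maximal cliques of the exclusivity network (Bron-Kerbosch with pivoting)."""
    return [frozenset(c) for c in nx.find_cliques(network.graph)]


# ---------------------------------------------------------------------------
# greedy expansion

def candidate_pool(
    members: Iterable[str],
    profile: BinaryAlterationProfile,
    hallmark_genes: HallmarkGeneSet,
    *,
    pool_alpha: float = 0.05,
    exclusivity_target: Literal["union", "per_member"] = "union",
) -> set[str]:
    """Genes eligible to join the module in the next greedy step.

    A candidate must (i) be in the profile, (ii) if protein-coding,
    belong to the module's hallmark (lncRNAs are exempt), (iii) be
    significantly mutually exclusive with the module's current
    alterations, and (iv) overlap every current member in fewer samples
    than either gene's unique alterations.
    """
    members = set(members)
    X = profile.matrix.to_numpy(dtype=bool)
    col_idx = {g: i for i, g in enumerate(profile.genes)}
    midx = np.array([col_idx[g] for g in members], dtype=int)
    union_vec = np.logical_or.reduce(X[:, midx], axis=1)
    member_vecs = {m: X[:, col_idx[m]] for m in members}

    pool: set[str] = set()
    for g in profile.genes:
        if g in members:
            continue
        if profile.gene_class[g] == "pcg" and g not in hallmark_genes.genes:
            continue
        vg = X[:, col_idx[g]]
        if not vg.any():
            continue
        if exclusivity_target == "union":
            p, _ = pair_test(vg, union_vec)
            if p >= pool_alpha:
                continue
        else:
            if any(pair_test(vg, vm)[0] >= pool_alpha for vm in member_vecs.values()):
                continue
        ok = True
        for vm in member_vecs.values():
            both = int(np.sum(vg & vm))
            if both >= int(np.sum(vg & ~vm)) or both >= int(np.sum(vm & ~vg)):
                ok = False
                break
        if ok:
            pool.add(g)
    return pool


def greedy_expand(
    seed: Iterable[str],
    profile: BinaryAlterationProfile,
    hallmark_genes: HallmarkGeneSet,
    *,
    alpha_const: float = 1.0,
    pool_alpha: float = 0.05,
    exclusivity_target: Literal["union", "per_member"] = "union",
) -> Module:
    """Expand a clique seed by repeatedly adding the candidate that maximises F.

    Each iteration rebuilds the candidate pool, scores every expanded
    set, and accepts the best addition only if it strictly improves F;
    the loop stops when the pool is empty or no candidate improves F,
    so the F trace is strictly increasing.
    """
    members = set(seed)
    if not members:
        raise ValueError("seed must be non-empty")
    current_f = mex_score(members, profile, alpha_const)
    while True:
        pool = candidate_pool(
            members,
            profile,
            hallmark_genes,
            pool_alpha=pool_alpha,
            exclusivity_target=exclusivity_target,
        )
        if not pool:
            break
        best_gene, best_f = None, current_f
        for g in sorted(pool):  # sorted: deterministic tie-break by gene id
            f = mex_score(members | {g}, profile, alpha_const)
            if f > best_f:
                best_gene, best_f = g, f
        if best_gene is None:
            break
        members.add(best_gene)
        current_f = best_f
    gammas = {g: int(profile.gamma[g]) for g in members}
    sub = profile.matrix[sorted(members)].to_numpy(dtype=bool)
    coverage = int(np.any(sub, axis=1).sum())
    return Module(
        members=frozenset(members),
        hallmark=hallmark_genes.hallmark,
        f_score=current_f,
        coverage=coverage,
        member_gammas=gammas,
        alpha_const=alpha_const,
    )


# ---------------------------------------------------------------------------
# permutation null

def rewire_profile(
    profile: BinaryAlterationProfile,
    rng: np.random.Generator | int,
    *,
    swap_factor: int = 10,
) -> BinaryAlterationProfile:
    """Margin-preserving randomisation of the profile (sample and gene rates kept)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mat = profile.matrix.to_numpy(dtype=np.int8)
    new = rewire_binary_matrix(mat, rng, swap_factor=swap_factor)
    if np.array_equal(new, mat) and mat.sum() >= 2:
        logger.warning("rewiring left the matrix unchanged (degenerate margins?)")
    return BinaryAlterationProfile(
        pd.DataFrame(new, index=profile.samples, columns=profile.genes),
        profile.alteration_sign.copy(),
        profile.gene_class.copy(),
    )


def permutation_pvalues(
    profile: BinaryAlterationProfile,
    member_sets: Sequence[frozenset[str]],
    n_perm: int,
    rng: np.random.Generator | int,
    *,
    alpha_const: float = 1.0,
    swap_factor: int = 10,
    tie_break: Literal["strict", "add_one", "randomized"] = "strict",
) -> np.ndarray:
    """Empirical p for several modules against one shared set of rewired profiles.

    For fixed members, the rewiring preserves every Gamma(g), so F
    exceeds its observed value exactly when the permuted coverage
    Gamma(M) does; coverages are compared as integers, which makes the
    test exact and bit-reproducible. ``tie_break`` controls how
    permutations tying the observed statistic count: "strict" follows
    the fraction-greater rule (ties favour significance), "add_one"
    applies (b+1)/(n+1) smoothing, and "randomized" splits ties
    uniformly (the variant whose null p is exactly uniform, used for
    calibration checks).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = profile.matrix.to_numpy(dtype=np.int8)
    col_idx = {g: i for i, g in enumerate(profile.genes)}
    idx_sets = [np.array(sorted(col_idx[g] for g in ms), dtype=int) for ms in member_sets]
    obs = np.array(
        [int(np.logical_or.reduce(X[:, idx].astype(bool), axis=1).sum()) for idx in idx_sets]
    )
    greater = np.zeros(len(idx_sets), dtype=np.int64)
    equal = np.zeros(len(idx_sets), dtype=np.int64)
    for _ in range(n_perm):
        Xp = rewire_binary_matrix(X, rng, swap_factor=swap_factor).astype(bool)
        for j, idx in enumerate(idx_sets):
            cov = int(np.logical_or.reduce(Xp[:, idx], axis=1).sum())
            if cov > obs[j]:
                greater[j] += 1
            elif cov == obs[j]:
                equal[j] += 1
    if tie_break == "strict":
        return greater / n_perm
    if tie_break == "add_one":
        return (greater + 1) / (n_perm + 1)
    if tie_break == "randomized":
        u = rng.random(len(idx_sets))
        return (greater + u * equal) / n_perm
    raise ValueError(f"unknown tie_break {tie_break!r}")


def permutation_test(
    module: Module,
    profile: BinaryAlterationProfile,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> float:
    """Empirical permutation p for one module's F score."""
    p = permutation_pvalues(
        profile, [module.members], n_perm, np.random.default_rng(rng), **kwargs
    )
    return float(p[0])


# ---------------------------------------------------------------------------
# selection

def select_modules(
    modules: list[Module],
    alpha: float = 0.05,
    *,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> list[Module]:
    """Multiple-testing correction and selection of candidate modules.

    Identical (hallmark, member-set) duplicates are collapsed before
    adjustment; Bonferroni (family-wise, the default) or Benjamini-
    Hochberg is applied over the m retained modules.
    """
    seen: dict[tuple[str, frozenset[str]], Module] = {}
    for mod in modules:
        if mod.p_empirical is None:
            raise ValueError("all modules must carry an empirical p before selection")
        seen.setdefault((mod.hallmark, mod.members), mod)
    unique = list(seen.values())
    m = len(unique)
    if m == 0:
        return []
    pvals = np.array([mod.p_empirical for mod in unique])
    if correction == "bonferroni":
        adjusted = np.minimum(1.0, pvals * m)
    elif correction == "bh":
        adjusted = stats.false_discovery_control(pvals, method="bh")
    else:
        raise ValueError(f"unknown correction {correction!r}")
    kept = []
    for mod, adj in zip(unique, adjusted):
        mod.p_adjusted = float(adj)
        if adj < alpha:
            kept.append(mod)
    return kept


# ---------------------------------------------------------------------------
# meta-genes

def merge_meta_genes(
    network: MexNetwork, annotation: GeneAnnotation
) -> tuple[MexNetwork, list[MetaGene], dict[str, str]]:
    """Collapse same-cytoband genes with identical network neighbourhoods.

    Genomic proximity inflates concurrent alteration, so genes on the
    same chromosome band whose neighbour sets (each excluding the
    other) coincide are one signal; they merge into a meta-gene whose
    representative is the lexicographically smallest member
    (deterministic). Returns the collapsed network, the meta-genes, and
    a gene -> representative map.
    """
    g = network.graph
    parent: dict[str, str] = {n: n for n in g.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_band: dict[str, list[str]] = {}
    for n in g.nodes:
        if n in annotation:
            by_band.setdefault(annotation[n].cytoband, []).append(n)
    for band, genes in by_band.items():
        for u, v in itertools.combinations(sorted(genes), 2):
            nu = set(g.neighbors(u)) - {v}
            nv = set(g.neighbors(v)) - {u}
            if nu == nv:
                union(u, v)

    groups: dict[str, set[str]] = {}
    for n in g.nodes:
        groups.setdefault(find(n), set()).add(n)

    gene_to_meta = {n: find(n) for n in g.nodes}
    metas = []
    merged = nx.Graph(hallmark=network.hallmark)
    for rep, members in groups.items():
        band = annotation[rep].cytoband if rep in annotation else "NA"
        if len(members) > 1:
            metas.append(MetaGene(meta_id=f"{band}|{rep}", members=frozenset(members), cytoband=band))
        merged.add_node(rep, **g.nodes[rep])
    for u, v, data in g.edges(data=True):
        ru, rv = find(u), find(v)
        if ru != rv and not merged.has_edge(ru, rv):
            merged.add_edge(ru, rv, **data)
    return MexNetwork(network.hallmark, merged), metas, gene_to_meta


def module_size_meta(module: Module, gene_to_meta: dict[str, str]) -> int:
    """Module size counted in meta-gene units."""
    return len({gene_to_meta.get(g, g) for g in module.members})


# ---------------------------------------------------------------------------
# full discovery for one run

def discover_modules(
    profile: BinaryAlterationProfile,
    hallmark_gene_sets: Sequence[HallmarkGeneSet],
    *,
    edge_alpha: float = 0.05,
    pool_alpha: float = 0.05,
    alpha_const: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
    module_alpha: float = 0.05,
    swap_factor: int = 10,
    tie_break: Literal["strict", "add_one", "randomized"] = "strict",
) -> tuple[list[Module], list[Module], dict[str, MexNetwork]]:
    """Seed, expand, permute and select modules across all hallmarks.

    Returns (selected modules, all scored modules, per-hallmark
    networks). One shared set of ``n_perm`` rewired profiles serves all
    modules of the run.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    networks: dict[str, MexNetwork] = {}
    expanded: list[Module] = []
    for hset in hallmark_gene_sets:
        net = build_network(profile, hset, alpha=edge_alpha)
        networks[hset.hallmark] = net
        for clique in maximal_cliques(net):
            mod = greedy_expand(
                clique,
                profile,
                hset,
                alpha_const=alpha_const,
                pool_alpha=pool_alpha,
            )
            if mod.size >= 2:
                expanded.append(mod)
    # deduplicate before the (expensive) permutation stage
    unique: dict[tuple[str, frozenset[str]], Module] = {}
    for mod in expanded:
        unique.setdefault((mod.hallmark, mod.members), mod)
    mods = list(unique.values())
    if mods:
        pvals = permutation_pvalues(
            profile,
            [m.members for m in mods],
            n_perm,
            rng,
            alpha_const=alpha_const,
            swap_factor=swap_factor,
            tie_break=tie_break,
        )
        for mod, p in zip(mods, pvals):
            mod.p_empirical = float(p)
    selected = select_modules(mods, module_alpha, correction=correction)
    return selected, mods, networks
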