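"""Functional assessment of modules: does the alteration move hallmark biology?

Samples are split by whether any module member is altered; protein-
coding genes differentially expressed between the two groups are
collected and tested for GO-term over-representation. A module is
confirmed when at least one enriched term belongs to its hallmark's
term set.

The differential-expression backend is a self-contained two-sided
rank-sum test on log2(x + 1) values with Benjamini-Hochberg FDR,
exposed behind a pluggable callable so a moderated-statistics backend
can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryAlterationProfile, ExpressionMatrix, HallmarkTermSet, Module
from .ontology import GoDag, hypergeom_enrichment

logger = logging.getLogger(__name__)


@dataclass
class ModuleAssessment:
    module_id: str
    hallmark: str
    n_altered: int
    n_unaltered: int
    de_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    enriched_terms: pd.DataFrame = field(default_factory=pd.DataFrame)
    hallmark_match: bool = False
    skipped: bool = False


def split_samples(
    module: Module, profile: BinaryAlterationProfile
) -> tuple[set[str], set[str]]:
    """Samples altered in >=1 module member vs the complement."""
    members = sorted(module.members)
    missing = [g for g in members if g not in profile.matrix.columns]
    if missing:
        raise KeyError(f"module members absent from profile: {missing}")
    sub = profile.matrix[members].to_numpy(dtype=bool)
    mask = np.any(sub, axis=1)
    samples = np.array(profile.samples)
    return set(samples[mask]), set(samples[~mask])


def ranksum_de(
    expr: ExpressionMatrix,
    group_a: set[str],
    group_b: set[str],
    *,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression by rank-sum on log2(x + 1).

    Constant genes get p = 1. Returns the full per-gene table
    (gene_id, log2fc, p, fdr, significant) sorted by p.
    """
    a_cols = [s for s in expr.samples if s in group_a]
    b_cols = [s for s in expr.samples if s in group_b]
    if len(a_cols) < 3 or len(b_cols) < 3:
        raise ValueError("each group needs at least 3 samples for DE testing")
    log = np.log2(expr.values.to_numpy(dtype=float) + 1.0)
    frame = pd.DataFrame(log, index=expr.genes, columns=expr.samples)
    xa = frame[a_cols].to_numpy()
    xb = frame[b_cols].to_numpy()
    pvals = np.ones(len(expr.genes))
    for i in range(len(expr.genes)):
        row = np.concatenate([xa[i], xb[i]])
        if np.all(row == row[0]):
            continue
        pvals[i] = stats.mannwhitneyu(xa[i], xb[i], alternative="two-sided").pvalue
    table = pd.DataFrame(
        {
            "gene_id": expr.genes,
            "log2fc": xa.mean(axis=1) - xb.mean(axis=1),
            "p": pvals,
        }
    )
    table["fdr"] = stats.false_discovery_control(table["p"], method="bh")
    table["significant"] = table["fdr"] < alpha_fdr
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


DEBackend = Callable[..., pd.DataFrame]


def differential_expression(
    expr: ExpressionMatrix,
    groups: tuple[set[str], set[str]],
    alpha_fdr: float = 0.05,
    backend: DEBackend = ranksum_de,
) -> pd.DataFrame:
    """Differentially expressed genes between two sample groups (FDR < alpha)."""
    table = backend(expr, groups[0], groups[1], alpha_fdr=alpha_fdr)
    return table[table["significant"]].reset_index(drop=True)


def go_enrichment(
    de_genes: set[str],
    background: set[str],
    dag: GoDag,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of DE genes (BH FDR < alpha).

    Annotations are propagated up is_a paths before counting; terms
    with no annotated background gene are absent from the table.
    """
    if not de_genes:
        return pd.DataFrame(columns=["set_name", "n_set", "n_overlap", "p", "fdr"])
    ann = dag.propagated_annotations()
    term_sets: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        if gene in background:
            for t in terms:
                term_sets.setdefault(t, set()).add(gene)
    table = hypergeom_enrichment(de_genes & background, term_sets, background)
    return table[table["fdr"] < alpha_fdr].reset_index(drop=True)


def hallmark_match(enriched_terms: set[str], hallmark_terms: HallmarkTermSet) -> bool:
    """True iff any enriched term belongs to the module's hallmark term set."""
    return bool(enriched_terms & hallmark_terms.terms)


def assess_module(
    module: Module,
    module_id: str,
    profile: BinaryAlterationProfile,
    expr: ExpressionMatrix,
    dag: GoDag,
    hallmark_terms: Mapping[str, HallmarkTermSet],
    *,
    pcg_background: set[str],
    alpha_fdr: float = 0.05,
    de_backend: DEBackend = ranksum_de,
) -> ModuleAssessment:
    """Full assessment of one module: split, DE, GO enrichment, hallmark check."""
    altered, unaltered = split_samples(module, profile)
    out = ModuleAssessment(
        module_id=module_id,
        hallmark=module.hallmark,
        n_altered=len(altered),
        n_unaltered=len(unaltered),
    )
    if len(altered) < 3 or len(unaltered) < 3:
        logger.warning("module %s: group too small (%d/%d); assessment skipped",
                       module_id, len(altered), len(unaltered))
        out.skipped = True
        return out
    pcg_rows = [g for g in expr.genes if g in pcg_background]
    expr_pcg = ExpressionMatrix(expr.values.loc[pcg_rows], expr.unit)
    de = differential_expression(expr_pcg, (altered, unaltered), alpha_fdr, de_backend)
    out.de_genes = de
    enriched = go_enrichment(set(de["gene_id"]), set(pcg_rows), dag, alpha_fdr)
    out.enriched_terms = enriched
    hset = hallmark_terms.get(module.hallmark)
    if hset is not None and not enriched.empty:
        out.hallmark_match = hallmark_match(set(enriched["set_name"]), hset)
    return out
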