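"""Screening candidate lncRNAs for proximal known-driver confounding.

A candidate lncRNA sitting antisense to, or within 10 kb of, a
protein-coding gene that is itself a copy-number-affected known driver
in the same cancer is plausibly a passenger of that driver's
alteration and is excluded.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .datatypes import CnaCallSet, ExpressionMatrix, GeneAnnotation, GeneRecord, ProximityHit
from .profile import (
    concordance_test,
    detectability_filter,
    dominant_alteration,
    frequency_filter,
)

logger = logging.getLogger(__name__)


def _gap(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def proximity_scan(
    lncrnas: Iterable[GeneRecord],
    pcgs: Iterable[GeneRecord],
    max_dist: int = 10_000,
) -> list[ProximityHit]:
    """All lncRNA-PCG pairs that are antisense-overlapping or same-strand proximal.

    Opposite strands: only overlapping pairs are reported (distance 0).
    Same strand: pairs whose closest-point gap is <= ``max_dist``
    (inclusive, per "within 10 kb"); same-strand overlap counts as
    distance 0. Pairs on different chromosomes are never reported.
    """
    pcgs_by_chrom: dict[str, list[GeneRecord]] = {}
    for p in pcgs:
        pcgs_by_chrom.setdefault(p.chrom, []).append(p)
    hits: list[ProximityHit] = []
    for lnc in lncrnas:
        for pcg in pcgs_by_chrom.get(lnc.chrom, ()):
            gap = _gap(lnc, pcg)
            overlapping = gap == 0 and lnc.start < pcg.end and pcg.start < lnc.end
            if lnc.strand != pcg.strand:
                if overlapping:
                    hits.append(ProximityHit(lnc.gene_id, pcg.gene_id, "opposite_strand_overlap", 0))
            elif gap <= max_dist:
                hits.append(ProximityHit(lnc.gene_id, pcg.gene_id, "same_strand_within_10kb", gap))
    return hits


def is_known_driver(
    pcg_id: str,
    driver_catalog: set[str],
    calls: CnaCallSet,
    expr: ExpressionMatrix,
    *,
    min_fraction: float = 0.025,
    rpkm_threshold: float = 0.3,
    detect_fraction: float = 0.3,
    alpha: float = 0.05,
) -> bool:
    """Catalog membership plus the frequency/detectability/concordance triple filter."""
    if pcg_id not in driver_catalog:
        return False
    if pcg_id not in calls.calls.columns or pcg_id not in expr.values.index:
        logger.warning("catalog gene %s absent from CNA/expression data; not a driver here", pcg_id)
        return False
    shared = [s for s in calls.samples if s in set(expr.samples)]
    sub = CnaCallSet(calls.calls.loc[shared])
    sign, altered = dominant_alteration(sub, pcg_id)
    counts = pd.Series({pcg_id: len(altered)}, dtype=int)
    if pcg_id not in frequency_filter(counts, len(shared), min_fraction):
        return False
    expr_sub = ExpressionMatrix(expr.values.loc[[pcg_id], shared], expr.unit)
    if pcg_id not in detectability_filter(expr_sub, rpkm_threshold, detect_fraction):
        return False
    if len(altered) in (0, len(shared)):
        return False
    return concordance_test(altered, sign, expr_sub.values.loc[pcg_id]) < alpha


def filter_candidates(
    candidates: set[str],
    hits: list[ProximityHit],
    driver_flags: dict[str, bool],
) -> tuple[set[str], pd.DataFrame]:
    """Drop candidates with >=1 proximity hit to a flagged driver PCG.

    Returns the retained candidate set and an exclusion report listing
    every excluded lncRNA with the hit responsible.
    """
    rows = []
    excluded: set[str] = set()
    for hit in hits:
        if hit.lncrna_id in candidates and driver_flags.get(hit.pcg_id, False):
            excluded.add(hit.lncrna_id)
            rows.append((hit.lncrna_id, hit.pcg_id, hit.relation, hit.distance_bp))
    report = pd.DataFrame(rows, columns=["lncrna_id", "pcg_id", "relation", "distance_bp"])
    return candidates - excluded, report
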