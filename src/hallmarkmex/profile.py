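"""Construction of the filtered binary alteration profile.

A gene enters the profile only if (i) its dominant-type high-level
event recurs in at least ``min_fraction`` of samples, (ii) it is
detectably expressed (RPKM > threshold in at least a given fraction of
samples), and (iii) its copy-number state concordantly shifts its own
expression (one-tailed rank test, p < alpha). Low-level calls (+/-1)
are ignored throughout.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AlterationSign,
    BinaryAlterationProfile,
    CnaCallSet,
    ExpressionMatrix,
    GeneAnnotation,
)

logger = logging.getLogger(__name__)


def dominant_alteration(calls: CnaCallSet, gene: str) -> tuple[AlterationSign, frozenset[str]]:
    """Dominant high-level event type of ``gene`` and the samples carrying it.

    Only calls of +2 (amplification) or -2 (homozygous deletion) count.
    The dominant type is the one seen in more samples; ties go to
    amplification (deterministic, logged).
    """
    if gene not in calls.calls.columns:
        raise KeyError(f"gene {gene!r} not in call set")
    col = calls.calls[gene]
    amp = frozenset(col.index[col == 2])
    dele = frozenset(col.index[col == -2])
    if len(amp) == len(dele) and len(amp) > 0:
        logger.debug("gene %s: amp/del tie (%d each); amp wins", gene, len(amp))
    if len(amp) >= len(dele):
        return "amp", amp
    return "del", dele


def frequency_filter(
    altered_counts: pd.Series, n_samples: int, min_fraction: float = 0.025
) -> set[str]:
    """Genes whose dominant-event count reaches ``min_fraction`` of samples (inclusive)."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    if n_samples == 0 or altered_counts.empty:
        raise ValueError("empty profile: no samples or no genes")
    frac = altered_counts / n_samples
    return set(frac.index[frac >= min_fraction])


def detectability_filter(
    expr: ExpressionMatrix, threshold: float = 0.3, fraction: float = 0.3
) -> set[str]:
    """Genes expressed strictly above ``threshold`` RPKM in at least ``fraction`` of samples."""
    if expr.unit != "rpkm":
        raise ValueError(f"detectability filter requires RPKM input, got unit={expr.unit!r}")
    detected = (expr.values.to_numpy() > threshold).mean(axis=1)
    return {g for g, f in zip(expr.genes, detected) if f >= fraction}


def concordance_test(
    altered: Iterable[str], sign: AlterationSign, expr_row: pd.Series
) -> float:
    """One-tailed rank-sum p that expression tracks the copy-number event.

    Amplified genes are tested for higher expression in altered samples,
    deleted genes for lower. Uses the Mann-Whitney U test (exact for
    small tie-free groups, normal approximation with continuity
    correction otherwise).
    """
    altered = set(altered)
    x = expr_row.loc[[s for s in expr_row.index if s in altered]].to_numpy(dtype=float)
    y = expr_row.loc[[s for s in expr_row.index if s not in altered]].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both altered and unaltered groups must be non-empty")
    alternative = "greater" if sign == "amp" else "less"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.pvalue)


def build_profile(
    calls: CnaCallSet,
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    *,
    min_fraction: float = 0.025,
    rpkm_threshold: float = 0.3,
    detect_fraction: float = 0.3,
    alpha: float = 0.05,
) -> BinaryAlterationProfile:
    """Build the binary alteration profile from calls, expression and annotation.

    Sample ids are intersected between the call set and the expression
    matrix; genes must be present in all three inputs and pass the
    frequency, detectability and concordance filters.
    """
    shared_samples = [s for s in calls.samples if s in set(expr.samples)]
    n_dropped = (len(calls.samples) - len(shared_samples)) + (
        len(expr.samples) - len(shared_samples)
    )
    if n_dropped:
        logger.info("sample-id mismatch: %d ids outside the CNA/expression intersection", n_dropped)
    if not shared_samples:
        raise ValueError("no shared samples between CNA calls and expression")

    sub_calls = CnaCallSet(calls.calls.loc[shared_samples])
    genes = [g for g in calls.genes if g in set(expr.genes) and g in annotation]

    dominant: dict[str, tuple[AlterationSign, frozenset[str]]] = {
        g: dominant_alteration(sub_calls, g) for g in genes
    }
    counts = pd.Series({g: len(ev) for g, (_, ev) in dominant.items()}, dtype=int)
    if counts.empty:
        logger.warning("no genes shared between calls, expression and annotation")
        return _empty_profile(shared_samples)

    freq_pass = frequency_filter(counts, len(shared_samples), min_fraction)
    expr_shared = ExpressionMatrix(expr.values.loc[genes, shared_samples], expr.unit)
    detect_pass = detectability_filter(expr_shared, rpkm_threshold, detect_fraction)

    keep: list[str] = []
    for g in genes:
        if g not in freq_pass or g not in detect_pass:
            continue
        sign, ev = dominant[g]
        if len(ev) == len(shared_samples):
            logger.warning("gene %s altered in every sample; concordance undefined, dropped", g)
            continue
        p = concordance_test(ev, sign, expr_shared.values.loc[g])
        if p < alpha:
            keep.append(g)

    if not keep:
        logger.warning("no genes survive the profile filters; returning empty profile")
        return _empty_profile(shared_samples)

    mat = pd.DataFrame(0, index=shared_samples, columns=keep, dtype=np.int8)
    signs = {}
    classes = {}
    for g in keep:
        sign, ev = dominant[g]
        mat.loc[list(ev), g] = 1
        signs[g] = sign
        classes[g] = annotation[g].gene_class
    return BinaryAlterationProfile(
        mat,
        pd.Series(signs, index=keep, name="sign"),
        pd.Series(classes, index=keep, name="class"),
    )


def _empty_profile(samples: list[str]) -> BinaryAlterationProfile:
    return BinaryAlterationProfile(
        pd.DataFrame(index=samples, dtype=np.int8),
        pd.Series(dtype=object, name="sign"),
        pd.Series(dtype=object, name="class"),
    )


def profile_from_calls(
    calls: CnaCallSet, annotation: GeneAnnotation, *, min_fraction: float | None = None
) -> BinaryAlterationProfile:
    """Binary profile of dominant-type events without expression-based filters.

    Convenience constructor used when expression is unavailable or when
    the alteration matrix itself is the object of study (e.g. planted
    synthetic profiles). Applies only the optional frequency filter.
    """
    genes = [g for g in calls.genes if g in annotation]
    dominant = {g: dominant_alteration(calls, g) for g in genes}
    counts = pd.Series({g: len(ev) for g, (_, ev) in dominant.items()}, dtype=int)
    if min_fraction is not None:
        keep = [g for g in genes if g in frequency_filter(counts, calls.n_samples, min_fraction)]
    else:
        keep = [g for g in genes if counts[g] > 0]
    mat = pd.DataFrame(0, index=calls.samples, columns=keep, dtype=np.int8)
    signs = {}
    classes = {}
    for g in keep:
        sign, ev = dominant[g]
        mat.loc[list(ev), g] = 1
        signs[g] = sign
        classes[g] = annotation[g].gene_class
    return BinaryAlterationProfile(
        mat, pd.Series(signs, index=keep, name="sign"), pd.Series(classes, index=keep, name="class")
    )
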