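"""Summary metrics for discovered modules and candidate lncRNAs.

Tissue specificity follows the normalisation-score index

    tau = sum_i (1 - exp_i / exp_max) / (n - 1),

0 for ubiquitous and 1 for single-tissue expression. The lncRNA
contribution of a module is the fraction of its covered samples
explained by at least one lncRNA member; coverage is Gamma(M) / N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BinaryAlterationProfile, Module, TissueExpression


def tissue_specificity(te: TissueExpression) -> float:
    """Normalisation-score tissue-specificity index in [0, 1]."""
    exp_max = float(te.exp.max())
    if exp_max <= 0:
        raise ValueError(f"{te.gene_id}: all-zero expression, score undefined")
    n = te.exp.shape[0]
    return float(np.sum(1.0 - te.exp / exp_max) / (n - 1))


def tissue_specificity_table(expr: pd.DataFrame) -> pd.Series:
    """Per-gene tissue specificity from a gene x tissue table; NaN for all-zero rows."""
    out = {}
    for gene, row in expr.iterrows():
        vals = row.to_numpy(dtype=float)
        if vals.max() <= 0:
            out[gene] = np.nan
        else:
            out[gene] = tissue_specificity(TissueExpression(str(gene), list(expr.columns), vals))
    return pd.Series(out, name="tissue_specificity")


def lncrna_contribution(module: Module, profile: BinaryAlterationProfile) -> float:
    """Fraction of the module's covered samples altered in >=1 lncRNA member.

    Samples altered in both a lncRNA and a PCG member count toward the
    numerator (union semantics). PCG-only modules contribute 0.
    """
    lnc_members = [g for g in module.members if profile.gene_class.get(g) == "lncrna"]
    if not lnc_members:
        return 0.0
    all_sub = profile.matrix[sorted(module.members)].to_numpy(dtype=bool)
    coverage = int(np.any(all_sub, axis=1).sum())
    if coverage == 0:
        return 0.0
    lnc_sub = profile.matrix[sorted(lnc_members)].to_numpy(dtype=bool)
    return float(np.any(lnc_sub, axis=1).sum() / coverage)


def coverage_fraction(module: Module, profile: BinaryAlterationProfile) -> float:
    """Gamma(M) / N: fraction of all samples altered in >=1 member."""
    n = profile.n_samples
    if n == 0:
        raise ValueError("empty profile")
    if not module.members:
        return 0.0
    sub = profile.matrix[sorted(module.members)].to_numpy(dtype=bool)
    return float(np.any(sub, axis=1).sum() / n)


def module_metrics_table(
    modules: list[Module], profile: BinaryAlterationProfile, module_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-module coverage and lncRNA-contribution summary."""
    ids = module_ids or [f"M{i + 1}" for i in range(len(modules))]
    rows = []
    for mid, mod in zip(ids, modules):
        rows.append(
            (
                mid,
                mod.hallmark,
                mod.size,
                coverage_fraction(mod, profile),
                lncrna_contribution(mod, profile),
            )
        )
    return pd.DataFrame(
        rows, columns=["module_id", "hallmark", "size", "coverage_fraction", "lncrna_contribution"]
    )
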