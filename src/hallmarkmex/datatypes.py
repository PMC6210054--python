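"""Core in-memory containers shared across the pipeline.

All tabular containers wrap pandas objects so that file round-trips,
alignment and subsetting use the standard DataFrame machinery; the
dataclasses add the invariants the pipeline relies on (value codes,
margin definitions, sign bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: The ten acquired capabilities of tumours used as functional categories.
HALLMARKS: tuple[str, ...] = (
    "Sustaining Proliferative Signaling",
    "Evading Growth Suppressors",
    "Resisting Cell Death",
    "Enabling Replicative Immortality",
    "Inducing Angiogenesis",
    "Tissue Invasion and Metastasis",
    "Genome Instability and Mutation",
    "Tumor-Promoting Inflammation",
    "Reprogramming Energy Metabolism",
    "Evading Immune Destruction",
)

GeneClass = Literal["pcg", "lncrna"]
AlterationSign = Literal["amp", "del"]

_VALID_CALLS = frozenset({-2, -1, 0, 1, 2})


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus: identity, biotype class and genomic span.

    Coordinates are 0-based half-open, BED-style.
    """

    gene_id: str
    gene_class: GeneClass
    chrom: str
    start: int
    end: int
    strand: str
    cytoband: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


class GeneAnnotation:
    """An annotation set: unique GeneRecords indexed by gene id."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            self._records[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    def __iter__(self):
        return iter(self._records.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        return GeneAnnotation(self._records[g] for g in gene_ids)

    def by_class(self, gene_class: GeneClass) -> list[GeneRecord]:
        return [r for r in self._records.values() if r.gene_class == gene_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.gene_id, r.gene_class, r.chrom, r.start, r.end, r.strand, r.cytoband)
                for r in self._records.values()
            ],
            columns=["gene_id", "class", "chrom", "start", "end", "strand", "cytoband"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneAnnotation":
        cols = ["gene_id", "class", "chrom", "start", "end", "strand", "cytoband"]
        return cls(
            GeneRecord(
                str(gene_id), str(cls_), str(chrom), int(start), int(end), str(strand), str(band)
            )
            for gene_id, cls_, chrom, start, end, strand, band in
            frame[cols].itertuples(index=False, name=None)
        )


@dataclass
class CnaCallSet:
    """Discrete gene-level copy-number calls, samples x genes.

    Values use the five-level GISTIC-thresholded code: -2 homozygous
    deletion, -1 shallow loss, 0 neutral, 1 low gain, 2 high-level
    amplification. Only +/-2 count as events downstream.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        vals = set(np.unique(self.calls.to_numpy()))
        bad = vals - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid copy-number codes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]


@dataclass
class ExpressionMatrix:
    """Expression values, genes x samples; RPKM or raw counts."""

    values: pd.DataFrame
    unit: Literal["rpkm", "count"] = "rpkm"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class BinaryAlterationProfile:
    """The filtered binary alteration profile every downstream stage consumes.

    ``matrix`` is samples x genes with entries in {0, 1}; a 1 marks a
    dominant-type high-level event. Per-gene column sums are the
    alteration counts Gamma(g); row and column sums together are the
    margins preserved by the permutation null.
    """

    matrix: pd.DataFrame
    alteration_sign: pd.Series  # gene -> "amp" | "del"
    gene_class: pd.Series  # gene -> "pcg" | "lncrna"

    def __post_init__(self) -> None:
        vals = set(np.unique(self.matrix.to_numpy())) if self.matrix.size else set()
        if not vals <= {0, 1}:
            raise ValueError("profile matrix must be binary")
        genes = list(self.matrix.columns)
        if list(self.alteration_sign.index) != genes or list(self.gene_class.index) != genes:
            raise ValueError("sign/class series must be indexed by the matrix columns")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def gamma(self) -> pd.Series:
        """Per-gene alteration counts Gamma(g) (column sums)."""
        return self.matrix.sum(axis=0)

    def altered_samples(self, gene: str) -> frozenset[str]:
        col = self.matrix[gene]
        return frozenset(col.index[col.astype(bool)])

    def lncrna_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "lncrna"])

    def pcg_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "pcg"])

    def subset_genes(self, genes: Iterable[str]) -> "BinaryAlterationProfile":
        genes = [g for g in genes if g in self.matrix.columns]
        return BinaryAlterationProfile(
            self.matrix[genes],
            self.alteration_sign.loc[genes],
            self.gene_class.loc[genes],
        )


@dataclass
class Module:
    """A mutually exclusive gene set with its exclusivity score and p-values.

    ``f_score`` is the exclusivity objective
    F = Gamma(M) / (sum_i Gamma(g_i) - Gamma(M) + alpha); ``coverage``
    is Gamma(M), the number of samples altered in at least one member.
    """

    members: frozenset[str]
    hallmark: str
    f_score: float
    coverage: int
    member_gammas: dict[str, int]
    alpha_const: float = 1.0
    p_empirical: float | None = None
    p_adjusted: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class MetaGene:
    """Equivalence class of co-located, identically connected genes."""

    meta_id: str
    members: frozenset[str]
    cytoband: str


@dataclass(frozen=True)
class ProximityHit:
    """A lncRNA/PCG proximity relation used for confounder screening."""

    lncrna_id: str
    pcg_id: str
    relation: Literal["opposite_strand_overlap", "same_strand_within_10kb"]
    distance_bp: int

    def __post_init__(self) -> None:
        if self.relation == "opposite_strand_overlap" and self.distance_bp != 0:
            raise ValueError("opposite-strand overlap implies distance 0")
        if self.distance_bp < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class HallmarkTermSet:
    """GO terms attached to one hallmark, with curated/expanded provenance."""

    hallmark: str
    terms: set[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        curated = {t for t, p in self.provenance.items() if p == "curated"}
        if not curated <= self.terms:
            raise ValueError("curated terms must be a subset of terms")

    @property
    def curated_terms(self) -> set[str]:
        return {t for t, p in self.provenance.items() if p == "curated"}


@dataclass
class HallmarkGeneSet:
    """Protein-coding genes attached to one hallmark."""

    hallmark: str
    genes: set[str]


@dataclass
class TissueExpression:
    """Expression of one gene across normal tissues (for Eq.-style tissue specificity)."""

    gene_id: str
    tissues: list[str]
    exp: np.ndarray

    def __post_init__(self) -> None:
        self.exp = np.asarray(self.exp, dtype=float)
        if len(self.tissues) != self.exp.shape[0]:
            raise ValueError("tissue list and expression vector length differ")
        if len(self.tissues) < 2:
            raise ValueError("tissue specificity needs at least 2 tissues")
        if (self.exp < 0).any():
            raise ValueError("expression must be nonnegative")
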