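"""Synthetic inputs with known ground truth.

The generator emulates every input the pipeline reads: discrete
copy-number calls with planted mutually exclusive modules over
independent Bernoulli background noise, expression with a log-scale
dosage response to high-level events, a small hallmark-rooted GO
forest with hallmark-coherent gene annotations, and non-overlapping
gene loci with strands and cytobands (optionally with planted
antisense/proximal lncRNA-PCG pairs). Everything is reproducible
bit-for-bit from its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    HALLMARKS,
    CnaCallSet,
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    HallmarkGeneSet,
    HallmarkTermSet,
)
from .ontology import GoDag, hallmark_genes


@dataclass
class PlantedModuleSpec:
    """Specification of one planted mutually exclusive module."""

    members: list[str]
    hallmark: str
    coverage: float  # fraction of samples covered by the module as a whole
    sign: str = "amp"  # "amp" or "del"
    overlap_rate: float = 0.0  # fraction of each member's block re-drawn freely


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated dataset."""

    planted_modules: list[PlantedModuleSpec]
    assignments: dict[str, list[str]]  # gene -> samples carrying its planted event
    background_rate: float
    dosage_effect: float
    rng_seed: int
    target_genes: dict[str, list[str]] = field(default_factory=dict)  # module hallmark -> PCGs

    def to_dict(self) -> dict:
        return {
            "planted_modules": [
                {
                    "members": m.members,
                    "hallmark": m.hallmark,
                    "coverage": m.coverage,
                    "sign": m.sign,
                    "overlap_rate": m.overlap_rate,
                }
                for m in self.planted_modules
            ],
            "assignments": {g: sorted(s) for g, s in self.assignments.items()},
            "background_rate": self.background_rate,
            "dosage_effect": self.dosage_effect,
            "rng_seed": self.rng_seed,
            "target_genes": self.target_genes,
        }


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def pcg_ids(n: int) -> list[str]:
    return [f"PCG{i:04d}" for i in range(1, n + 1)]


def lnc_ids(n: int) -> list[str]:
    return [f"LNC{i:04d}" for i in range(1, n + 1)]


def generate_profile(
    n_samples: int,
    n_pcgs: int,
    n_lncrnas: int,
    planted: Sequence[PlantedModuleSpec],
    background_rate: float,
    seed: int,
    *,
    dosage_effect: float = 2.0,
) -> tuple[CnaCallSet, SyntheticTruth]:
    """Copy-number calls with planted exclusive modules plus Bernoulli background.

    Each planted module's requested coverage is split into near-equal
    disjoint sample blocks, one per member, receiving +/-2 calls of the
    module's sign; every cell additionally receives an independent
    background high-level event (random sign) at ``background_rate``.
    """
    rng = np.random.default_rng(seed)
    samples = _sample_ids(n_samples)
    genes = pcg_ids(n_pcgs) + lnc_ids(n_lncrnas)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for spec in planted:
        missing = [g for g in spec.members if g not in gene_pos]
        if missing:
            raise ValueError(f"planted members not in gene universe: {missing}")
        if not 0 < spec.coverage <= 1:
            raise ValueError(f"planted coverage must be in (0, 1]: {spec.coverage}")
        if round(spec.coverage * n_samples) > n_samples:
            raise ValueError("planted coverage exceeds the sample count")
    calls = np.zeros((n_samples, len(genes)), dtype=np.int8)
    assignments: dict[str, list[str]] = {}
    for spec in planted:
        n_cov = int(round(spec.coverage * n_samples))
        chosen = rng.choice(n_samples, size=n_cov, replace=False)
        blocks = np.array_split(chosen, len(spec.members))
        value = 2 if spec.sign == "amp" else -2
        for gene, block in zip(spec.members, blocks):
            block = list(block)
            if spec.overlap_rate > 0:
                n_redraw = int(round(spec.overlap_rate * len(block)))
                if n_redraw:
                    keep = block[: len(block) - n_redraw]
                    extra = rng.choice(n_samples, size=n_redraw, replace=False)
                    block = sorted(set(keep) | set(extra))
            calls[np.asarray(block, dtype=int), gene_pos[gene]] = value
            assignments[gene] = [samples[i] for i in sorted(block)]
    if background_rate > 0:
        noise = rng.random(calls.shape) < background_rate
        signs = rng.choice(np.array([-2, 2], dtype=np.int8), size=calls.shape)
        calls = np.where((calls == 0) & noise, signs, calls)
    frame = pd.DataFrame(calls, index=samples, columns=genes)
    truth = SyntheticTruth(
        planted_modules=list(planted),
        assignments=assignments,
        background_rate=background_rate,
        dosage_effect=dosage_effect,
        rng_seed=seed,
    )
    return CnaCallSet(frame), truth


def generate_expression(
    calls: CnaCallSet,
    truth: SyntheticTruth,
    seed: int,
    *,
    baseline_mean: float = 3.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 0.5,
    target_effect: float = 1.5,
) -> ExpressionMatrix:
    """RPKM expression with a log2 dosage shift per high-level event.

    Per-gene log2 baselines are normal (log-normal RPKM); samples with
    a +2 call shift up and -2 down by the truth's ``dosage_effect``.
    Module target genes (downstream responders) shift by
    ``target_effect`` in samples where their module is altered,
    emulating a hallmark-wide transcriptional consequence.
    """
    rng = np.random.default_rng(seed)
    genes = calls.genes
    samples = calls.samples
    base = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    log2 = base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    cmat = calls.calls.to_numpy().T  # genes x samples
    log2 = log2 + truth.dosage_effect * (cmat == 2) - truth.dosage_effect * (cmat == -2)
    if truth.target_genes:
        gene_pos = {g: i for i, g in enumerate(genes)}
        sample_pos = {s: i for i, s in enumerate(samples)}
        for spec in truth.planted_modules:
            targets = truth.target_genes.get(spec.hallmark, [])
            if not targets:
                continue
            altered = sorted({s for g in spec.members for s in truth.assignments.get(g, [])})
            cols = [sample_pos[s] for s in altered]
            shift = target_effect if spec.sign == "amp" else -target_effect
            for t in targets:
                log2[gene_pos[t], cols] += shift
    rpkm = np.exp2(log2)
    return ExpressionMatrix(pd.DataFrame(rpkm, index=genes, columns=samples), unit="rpkm")


def generate_ontology(
    pcg_genes: Sequence[str],
    seed: int,
    *,
    n_hallmarks: int = 10,
    terms_per_hallmark: int = 6,
    curated_per_hallmark: int = 3,
    annotations_per_gene: int = 2,
    leak_rate: float = 0.0,
    gene_hallmarks: dict[str, str] | None = None,
) -> tuple[GoDag, list[HallmarkTermSet], set[str]]:
    """A hallmark-rooted GO forest with hallmark-coherent gene annotations.

    One global root; each hallmark owns an is_a subtree of
    ``terms_per_hallmark`` terms (random tree shape). The first
    ``curated_per_hallmark`` terms of each subtree form the curated
    set; the remainder are candidate terms. Genes are annotated to
    random terms of their assigned hallmark, leaking to another
    hallmark with probability ``leak_rate``.
    """
    if not 1 <= n_hallmarks <= len(HALLMARKS):
        raise ValueError(f"n_hallmarks must be in [1, {len(HALLMARKS)}]")
    if curated_per_hallmark > terms_per_hallmark:
        raise ValueError("curated_per_hallmark cannot exceed terms_per_hallmark")
    rng = np.random.default_rng(seed)
    hallmarks = list(HALLMARKS[:n_hallmarks])
    root = "GO:0000001"
    edges: list[tuple[str, str]] = []
    term_counter = 1
    hallmark_terms: dict[str, list[str]] = {}
    for h in hallmarks:
        terms = []
        for j in range(terms_per_hallmark):
            term_counter += 1
            tid = f"GO:{term_counter:07d}"
            if j == 0:
                edges.append((tid, root))
            else:
                parent = terms[int(rng.integers(0, len(terms)))]
                edges.append((tid, parent))
            terms.append(tid)
        hallmark_terms[h] = terms

    if gene_hallmarks is None:
        gene_hallmarks = {
            g: hallmarks[int(rng.integers(0, len(hallmarks)))] for g in pcg_genes
        }
    annotations: dict[str, set[str]] = {}
    for g in pcg_genes:
        h = gene_hallmarks.get(g)
        if h is None:
            continue
        own = hallmark_terms[h]
        n_ann = min(annotations_per_gene, len(own))
        picks = rng.choice(len(own), size=n_ann, replace=False)
        terms = {own[i] for i in picks}
        if leak_rate > 0 and len(hallmarks) > 1 and rng.random() < leak_rate:
            other = hallmarks[int(rng.integers(0, len(hallmarks)))]
            if other != h:
                terms.add(hallmark_terms[other][int(rng.integers(0, terms_per_hallmark))])
        annotations[g] = terms

    dag = GoDag(edges, terms=[root], annotations=annotations)
    curated = []
    candidates: set[str] = set()
    for h in hallmarks:
        terms = hallmark_terms[h]
        cur = set(terms[:curated_per_hallmark])
        curated.append(HallmarkTermSet(h, set(cur), {t: "curated" for t in cur}))
        candidates |= set(terms[curated_per_hallmark:])
    return dag, curated, candidates


def generate_annotation(
    genes: Sequence[tuple[str, str]],
    seed: int,
    *,
    n_chroms: int = 3,
    planted_pairs: Sequence[tuple[str, str, str, int]] = (),
    min_gap: int = 50_000,
    max_gap: int = 200_000,
    span_range: tuple[int, int] = (2_000, 20_000),
) -> GeneAnnotation:
    """Non-overlapping gene loci with strands and cytobands.

    ``planted_pairs`` entries are (lncrna_id, pcg_id, kind, gap) with
    kind "antisense_overlap" (gap ignored) or "same_strand_gap"; each
    pair is placed on its own chromosome, isolated from everything
    else, so a proximity scan finds exactly the planted relation.
    """
    rng = np.random.default_rng(seed)
    planted_ids = {g for pair in planted_pairs for g in pair[:2]}
    records: list[GeneRecord] = []
    pos = {c: 10_000 for c in range(n_chroms)}
    for gene_id, gene_class in genes:
        if gene_id in planted_ids:
            continue
        c = int(rng.integers(0, n_chroms))
        start = pos[c] + int(rng.integers(min_gap, max_gap))
        end = start + int(rng.integers(*span_range))
        pos[c] = end
        chrom = f"chr{c + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        band = f"{c + 1}{'p' if start < 5_000_000 else 'q'}{start // 1_000_000 + 1}"
        records.append(GeneRecord(gene_id, gene_class, chrom, start, end, strand, band))
    class_of = dict(genes)
    for i, (lnc, pcg, kind, gap) in enumerate(planted_pairs):
        chrom = f"chrP{i + 1}"
        band = f"P{i + 1}q1"
        if kind == "antisense_overlap":
            records.append(GeneRecord(pcg, class_of.get(pcg, "pcg"), chrom, 100_000, 110_000, "+", band))
            records.append(GeneRecord(lnc, class_of.get(lnc, "lncrna"), chrom, 104_000, 108_000, "-", band))
        elif kind == "same_strand_gap":
            records.append(GeneRecord(pcg, class_of.get(pcg, "pcg"), chrom, 100_000, 110_000, "+", band))
            records.append(GeneRecord(lnc, class_of.get(lnc, "lncrna"), chrom, 110_000 + gap, 114_000 + gap, "+", band))
        else:
            raise ValueError(f"unknown planted pair kind {kind!r}")
    return GeneAnnotation(records)


@dataclass
class SyntheticDataset:
    """A complete generated input bundle plus its ground truth."""

    calls: CnaCallSet
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    dag: GoDag
    curated_terms: list[HallmarkTermSet]
    candidate_terms: set[str]
    full_term_sets: list[HallmarkTermSet]
    hallmark_gene_sets: list[HallmarkGeneSet]
    truth: SyntheticTruth
    driver_catalog: set[str] = field(default_factory=set)


def default_fixture(
    seed: int,
    *,
    n_samples: int = 200,
    n_pcgs: int = 40,
    n_lncrnas: int = 20,
    n_modules: int = 3,
    module_size: int = 3,
    coverage: float = 0.6,
    background_rate: float = 0.02,
    dosage_effect: float = 2.0,
    targets_per_module: int = 6,
    n_hallmarks: int = 10,
    overlap_rate: float = 0.0,
) -> SyntheticDataset:
    """The default study conditions: 200 samples, three planted exclusive
    3-gene modules (two PCGs + one lncRNA each) at 60% coverage in three
    different hallmarks, 2% background noise, dosage effect 2."""
    pcgs = pcg_ids(n_pcgs)
    lncs = lnc_ids(n_lncrnas)
    planted = []
    n_planted_pcgs = n_modules * (module_size - 1)
    for i in range(n_modules):
        members = pcgs[i * (module_size - 1): (i + 1) * (module_size - 1)] + [lncs[i]]
        planted.append(
            PlantedModuleSpec(
                members=members,
                hallmark=HALLMARKS[i],
                coverage=coverage,
                sign="amp",
                overlap_rate=overlap_rate,
            )
        )
    calls, truth = generate_profile(
        n_samples, n_pcgs, n_lncrnas, planted, background_rate, seed,
        dosage_effect=dosage_effect,
    )
    # downstream responder PCGs, annotated to their module's hallmark
    free_pcgs = pcgs[n_planted_pcgs:]
    target_genes: dict[str, list[str]] = {}
    for i, spec in enumerate(planted):
        target_genes[spec.hallmark] = free_pcgs[
            i * targets_per_module: (i + 1) * targets_per_module
        ]
    truth.target_genes = target_genes
    expression = generate_expression(calls, truth, seed + 1)

    gene_hallmarks: dict[str, str] = {}
    for spec in planted:
        for g in spec.members:
            if g.startswith("PCG"):
                gene_hallmarks[g] = spec.hallmark
    for h, targets in target_genes.items():
        for g in targets:
            gene_hallmarks[g] = h
    rng = np.random.default_rng(seed + 2)
    hallmarks = list(HALLMARKS[:n_hallmarks])
    for g in pcgs:
        if g not in gene_hallmarks:
            gene_hallmarks[g] = hallmarks[int(rng.integers(0, len(hallmarks)))]
    dag, curated, candidates = generate_ontology(
        pcgs, seed + 3, n_hallmarks=n_hallmarks, gene_hallmarks=gene_hallmarks
    )
    # full term sets (curated + every candidate term of the hallmark subtree)
    full = _full_term_sets(dag, curated, candidates)
    hsets = hallmark_genes(full, dag)
    annotation = generate_annotation(
        [(g, "pcg") for g in pcgs] + [(g, "lncrna") for g in lncs], seed + 4
    )
    return SyntheticDataset(
        calls=calls,
        expression=expression,
        annotation=annotation,
        dag=dag,
        curated_terms=curated,
        candidate_terms=candidates,
        full_term_sets=full,
        hallmark_gene_sets=hsets,
        truth=truth,
    )


def _full_term_sets(
    dag: GoDag, curated: list[HallmarkTermSet], candidates: Iterable[str]
) -> list[HallmarkTermSet]:
    """Assign every candidate term to the hallmark whose curated subtree contains it."""
    out = []
    for hset in curated:
        # subtree membership: the hallmark's curated root is an ancestor
        roots = {t for t in hset.terms if not (dag.ancestors(t) & hset.terms)}
        terms = set(hset.terms)
        prov = dict(hset.provenance)
        for cand in candidates:
            if dag.ancestors(cand) & roots or cand in roots:
                terms.add(cand)
                prov.setdefault(cand, "expanded")
        out.append(HallmarkTermSet(hset.hallmark, terms, prov))
    return out


def noise_profile(
    n_samples: int,
    n_genes: int,
    rate: float,
    seed: int,
    *,
    n_lncrnas: int = 0,
):
    """A pure-noise binary alteration profile (no planted structure)."""
    from .datatypes import BinaryAlterationProfile

    rng = np.random.default_rng(seed)
    mat = (rng.random((n_samples, n_genes)) < rate).astype(np.int8)
    genes = pcg_ids(n_genes - n_lncrnas) + lnc_ids(n_lncrnas)
    classes = ["pcg"] * (n_genes - n_lncrnas) + ["lncrna"] * n_lncrnas
    frame = pd.DataFrame(mat, index=_sample_ids(n_samples), columns=genes)
    return BinaryAlterationProfile(
        frame,
        pd.Series(["amp"] * n_genes, index=genes, name="sign"),
        pd.Series(classes, index=genes, name="class"),
    )
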