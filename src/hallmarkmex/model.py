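"""Model/Results interface orchestrating the full discovery pipeline.

``HallmarkDriverModel`` holds the inputs (copy-number calls,
expression, gene annotation, hallmark gene/term sets, optional GO DAG
and driver catalog) and a :class:`RunConfig` of stage thresholds whose
defaults are the method's published operating point. ``fit`` runs
profile construction, per-hallmark network building, module discovery
with the permutation null, functional assessment, confounder
exclusion and summary metrics, returning a
:class:`HallmarkDriverResults` carrying every stage output, with
``summary()`` giving a compact human-readable account.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .assessment import ModuleAssessment, assess_module
from .confounders import filter_candidates, is_known_driver, proximity_scan
from .datatypes import (
    BinaryAlterationProfile,
    CnaCallSet,
    ExpressionMatrix,
    GeneAnnotation,
    HallmarkGeneSet,
    HallmarkTermSet,
    Module,
)
from .metrics import module_metrics_table
from .modules import discover_modules, merge_meta_genes, module_size_meta
from .network import MexNetwork
from .ontology import GoDag, derive_threshold, expand_terms, hallmark_genes
from .profile import build_profile

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Stage thresholds; the defaults are the method's published values."""

    min_freq: float = 0.025
    rpkm_threshold: float = 0.3
    detect_fraction: float = 0.3
    concordance_alpha: float = 0.05
    edge_alpha: float = 0.05
    pool_alpha: float = 0.05
    alpha_const: float = 1.0
    n_perm: int = 1000
    correction: Literal["bonferroni", "bh"] = "bonferroni"
    module_alpha: float = 0.05
    assess_fdr: float = 0.05
    max_dist: int = 10_000
    term_threshold: float | Literal["auto"] = "auto"
    swap_factor: int = 10
    skip_assess: bool = False
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HallmarkDriverResults:
    """Estimates and diagnostics from one fitted discovery run."""

    config: RunConfig
    profile: BinaryAlterationProfile
    networks: dict[str, MexNetwork]
    all_modules: list[Module]
    selected_modules: list[Module]
    confirmed_modules: list[Module]
    assessments: list[ModuleAssessment]
    candidate_lncrnas: set[str]
    retained_lncrnas: set[str]
    exclusion_report: pd.DataFrame
    metrics: pd.DataFrame
    gene_to_meta: dict[str, dict[str, str]] = field(default_factory=dict)
    term_threshold_used: float | None = None

    @property
    def modules_frame(self) -> pd.DataFrame:
        frame = hio.modules_frame(self.confirmed_modules)
        if self.gene_to_meta:
            sizes = [
                module_size_meta(m, self.gene_to_meta.get(m.hallmark, {}))
                for m in self.confirmed_modules
            ]
            frame.insert(3, "size_meta", sizes)
        return frame

    def summary(self) -> str:
        lines = []
        add = lines.append
        bar = "=" * 72
        add(bar)
        add("Hallmark-associated mutually exclusive module discovery")
        add(bar)
        add(f"Samples:                 {self.profile.n_samples}")
        n_pcg = len(self.profile.pcg_genes())
        n_lnc = len(self.profile.lncrna_genes())
        add(f"Profile genes:           {n_pcg + n_lnc} ({n_pcg} PCG, {n_lnc} lncRNA)")
        add(f"Hallmark networks:       {len(self.networks)}")
        n_edges = sum(n.graph.number_of_edges() for n in self.networks.values())
        add(f"Exclusivity edges:       {n_edges}")
        add(f"Modules tested:          {len(self.all_modules)}")
        add(
            f"Selected ({self.config.correction}, p<{self.config.module_alpha}): "
            f"{len(self.selected_modules)}"
        )
        add(f"Hallmark-confirmed:      {len(self.confirmed_modules)}")
        add(f"Candidate lncRNAs:       {len(self.candidate_lncrnas)}")
        add(f"After confounder filter: {len(self.retained_lncrnas)}")
        if not self.metrics.empty:
            add(
                "Mean coverage:           "
                f"{100 * self.metrics['coverage_fraction'].mean():.1f}% of samples"
            )
            add(
                "Mean lncRNA contribution:"
                f" {100 * self.metrics['lncrna_contribution'].mean():.1f}%"
            )
        add(bar)
        frame = self.modules_frame
        if not frame.empty:
            add(frame.to_string(index=False))
            add(bar)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write per-stage outputs plus a machine-readable manifest; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stages: dict[str, str] = {}
        hio.write_profile(self.profile, outdir / "profile_matrix.tsv", outdir / "profile_genes.tsv")
        stages["profile"] = "profile_matrix.tsv"
        for h, net in self.networks.items():
            fname = f"network_{h.replace(' ', '_')}.tsv"
            hio.write_network(net, outdir / fname)
        stages["networks"] = f"{len(self.networks)} edge lists"
        hio.write_modules(self.all_modules, outdir / "modules_all.tsv")
        stages["modules_all"] = "modules_all.tsv"
        hio.write_modules(self.selected_modules, outdir / "modules_selected.tsv")
        stages["modules_selected"] = "modules_selected.tsv"
        self.modules_frame.to_csv(outdir / "modules_confirmed.tsv", sep="\t", index=False,
                                  float_format="%.10g")
        stages["modules_confirmed"] = "modules_confirmed.tsv"
        self.exclusion_report.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        stages["exclusions"] = "exclusions.tsv"
        pd.DataFrame({"lncrna_id": sorted(self.retained_lncrnas)}).to_csv(
            outdir / "candidate_lncrnas.tsv", sep="\t", index=False
        )
        stages["candidates"] = "candidate_lncrnas.tsv"
        self.metrics.to_csv(outdir / "module_metrics.tsv", sep="\t", index=False,
                            float_format="%.10g")
        stages["metrics"] = "module_metrics.tsv"
        manifest = {
            "tool": "hallmarkmex",
            "version": __version__,
            "config": self.config.to_dict(),
            "seed": self.config.rng_seed,
            "stages": stages,
        }
        hio.write_json(manifest, outdir / "manifest.json")
        return manifest


class HallmarkDriverModel:
    """Discovery model for hallmark-associated candidate driver lncRNAs.

    Parameters
    ----------
    calls, expression, annotation
        The cancer cohort's gene-level copy-number calls, expression
        matrix and gene annotation.
    hallmark_gene_sets
        Hallmark -> protein-coding gene sets. If omitted, they are
        derived from ``go_dag`` + ``curated_term_sets`` by similarity
        expansion at the configured threshold.
    go_dag, hallmark_term_sets
        Needed for the functional-assessment stage.
    driver_catalog
        Known driver PCG ids for the confounder-exclusion stage.
    """

    def __init__(
        self,
        calls: CnaCallSet,
        expression: ExpressionMatrix,
        annotation: GeneAnnotation,
        hallmark_gene_sets: list[HallmarkGeneSet] | None = None,
        *,
        go_dag: GoDag | None = None,
        curated_term_sets: list[HallmarkTermSet] | None = None,
        hallmark_term_sets: list[HallmarkTermSet] | None = None,
        candidate_terms: set[str] | None = None,
        driver_catalog: set[str] | None = None,
        config: RunConfig | None = None,
    ):
        self.calls = calls
        self.expression = expression
        self.annotation = annotation
        self.hallmark_gene_sets = hallmark_gene_sets
        self.go_dag = go_dag
        self.curated_term_sets = curated_term_sets
        self.hallmark_term_sets = hallmark_term_sets
        self.candidate_terms = candidate_terms
        self.driver_catalog = driver_catalog or set()
        self.config = config or RunConfig()

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        cna_path: str | Path,
        expr_path: str | Path,
        annot_path: str | Path,
        *,
        hallmark_genes_gmt: str | Path | None = None,
        obo_path: str | Path | None = None,
        gene_annotations_path: str | Path | None = None,
        curated_gmt: str | Path | None = None,
        driver_list: str | Path | None = None,
        config: RunConfig | None = None,
    ) -> "HallmarkDriverModel":
        calls = hio.read_cna_calls(cna_path)
        expr = hio.read_expression(expr_path)
        annotation = hio.read_annotation(annot_path)
        hsets = None
        if hallmark_genes_gmt is not None:
            hsets = [
                HallmarkGeneSet(name, genes)
                for name, genes in hio.read_gmt(hallmark_genes_gmt).items()
            ]
        dag = None
        if obo_path is not None:
            ann = (
                hio.read_gene_annotations(gene_annotations_path)
                if gene_annotations_path
                else None
            )
            dag = hio.read_obo(obo_path, annotations=ann)
        curated = hio.read_hallmark_termsets(curated_gmt) if curated_gmt else None
        catalog = hio.read_gene_list(driver_list) if driver_list else None
        return cls(
            calls,
            expr,
            annotation,
            hsets,
            go_dag=dag,
            curated_term_sets=curated,
            driver_catalog=catalog,
            config=config,
        )

    @classmethod
    def from_synthetic(cls, seed: int = 0, config: RunConfig | None = None, **fixture_kwargs):
        """Model built on the default synthetic fixture; returns (model, truth)."""
        from .simulate import default_fixture

        data = default_fixture(seed, **fixture_kwargs)
        model = cls(
            data.calls,
            data.expression,
            data.annotation,
            data.hallmark_gene_sets,
            go_dag=data.dag,
            curated_term_sets=data.curated_terms,
            hallmark_term_sets=data.full_term_sets,
            candidate_terms=data.candidate_terms,
            driver_catalog=data.driver_catalog,
            config=config,
        )
        return model, data.truth

    # -- fitting -----------------------------------------------------------

    def _resolve_hallmark_sets(self) -> tuple[list[HallmarkGeneSet], float | None]:
        if self.hallmark_gene_sets is not None:
            return self.hallmark_gene_sets, None
        if self.go_dag is None or self.curated_term_sets is None:
            raise ValueError(
                "either hallmark_gene_sets or (go_dag + curated_term_sets) is required"
            )
        thr = self.config.term_threshold
        if thr == "auto":
            thr = derive_threshold(self.curated_term_sets, self.go_dag)
        candidates = self.candidate_terms
        if candidates is None:
            curated_all = {t for s in self.curated_term_sets for t in s.terms}
            candidates = self.go_dag.terms - curated_all
        termsets = expand_terms(sorted(candidates), self.curated_term_sets, self.go_dag, thr)
        if self.hallmark_term_sets is None:
            self.hallmark_term_sets = termsets
        return hallmark_genes(termsets, self.go_dag), float(thr)

    def fit(self, seed: int | None = None, n_perm: int | None = None) -> HallmarkDriverResults:
        cfg = self.config
        if seed is not None:
            cfg.rng_seed = seed
        if n_perm is not None:
            cfg.n_perm = n_perm
        rng = np.random.default_rng(cfg.rng_seed)

        hsets, thr_used = self._resolve_hallmark_sets()

        profile = build_profile(
            self.calls,
            self.expression,
            self.annotation,
            min_fraction=cfg.min_freq,
            rpkm_threshold=cfg.rpkm_threshold,
            detect_fraction=cfg.detect_fraction,
            alpha=cfg.concordance_alpha,
        )
        logger.info("profile: %d samples x %d genes", profile.n_samples, len(profile.genes))

        selected, all_mods, networks = discover_modules(
            profile,
            hsets,
            edge_alpha=cfg.edge_alpha,
            pool_alpha=cfg.pool_alpha,
            alpha_const=cfg.alpha_const,
            n_perm=cfg.n_perm,
            rng=rng,
            correction=cfg.correction,
            module_alpha=cfg.module_alpha,
            swap_factor=cfg.swap_factor,
        )

        gene_to_meta = {}
        for h, net in networks.items():
            _, _, mapping = merge_meta_genes(net, self.annotation)
            gene_to_meta[h] = mapping

        term_map: Mapping[str, HallmarkTermSet] = {
            s.hallmark: s for s in (self.hallmark_term_sets or [])
        }
        assessments: list[ModuleAssessment] = []
        confirmed: list[Module] = []
        if cfg.skip_assess:
            confirmed = list(selected)
        elif self.go_dag is not None and term_map:
            pcg_bg = {
                g
                for g in self.expression.genes
                if g in self.annotation and self.annotation[g].gene_class == "pcg"
            }
            for i, mod in enumerate(selected):
                a = assess_module(
                    mod,
                    f"M{i + 1}",
                    profile,
                    self.expression,
                    self.go_dag,
                    term_map,
                    pcg_background=pcg_bg,
                    alpha_fdr=cfg.assess_fdr,
                )
                assessments.append(a)
                if a.hallmark_match:
                    confirmed.append(mod)
        else:
            confirmed = list(selected)

        candidate_lncs = {
            g
            for mod in confirmed
            for g in mod.members
            if profile.gene_class.get(g) == "lncrna"
        }
        if self.driver_catalog:
            lnc_recs = [self.annotation[g] for g in candidate_lncs if g in self.annotation]
            pcg_recs = self.annotation.by_class("pcg")
            hits = proximity_scan(lnc_recs, pcg_recs, cfg.max_dist)
            flags = {
                hit.pcg_id: is_known_driver(
                    hit.pcg_id,
                    self.driver_catalog,
                    self.calls,
                    self.expression,
                    min_fraction=cfg.min_freq,
                    rpkm_threshold=cfg.rpkm_threshold,
                    detect_fraction=cfg.detect_fraction,
                    alpha=cfg.concordance_alpha,
                )
                for hit in hits
            }
            retained, report = filter_candidates(candidate_lncs, hits, flags)
        else:
            retained = set(candidate_lncs)
            report = pd.DataFrame(columns=["lncrna_id", "pcg_id", "relation", "distance_bp"])

        metrics = module_metrics_table(confirmed, profile)

        return HallmarkDriverResults(
            config=cfg,
            profile=profile,
            networks=networks,
            all_modules=all_mods,
            selected_modules=selected,
            confirmed_modules=confirmed,
            assessments=assessments,
            candidate_lncrnas=candidate_lncs,
            retained_lncrnas=retained,
            exclusion_report=report,
            metrics=metrics,
            gene_to_meta=gene_to_meta,
            term_threshold_used=thr_used,
        )


def run_all(
    model: HallmarkDriverModel, outdir: str | Path, seed: int | None = None
) -> HallmarkDriverResults:
    """Fit the model and persist every stage output plus the manifest."""
    results = model.fit(seed=seed)
    results.save(outdir)
    return results
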