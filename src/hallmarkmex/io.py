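"""Readers and writers for the plain-text interchange formats.

All tables are TSV with header rows and "NA" for missing values.
Ontologies travel as OBO 1.2 (parsed with obonet), gene sets as GMT,
annotations as 7-column TSV with 0-based half-open coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import obonet
import pandas as pd

from .datatypes import (
    BinaryAlterationProfile,
    CnaCallSet,
    ExpressionMatrix,
    GeneAnnotation,
    HallmarkTermSet,
    Module,
)
from .network import MexNetwork
from .ontology import GoDag

NA = "NA"


# -- matrices ---------------------------------------------------------------

def read_cna_calls(path: str | Path) -> CnaCallSet:
    """CNA TSV: first column sample id, header = gene ids, integer cells."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CnaCallSet(frame.astype(int))


def write_cna_calls(calls: CnaCallSet, path: str | Path) -> None:
    calls.calls.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path: str | Path, unit: str = "rpkm") -> ExpressionMatrix:
    """Expression TSV: first column gene id, header = sample ids, real cells."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame.astype(float), unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# -- annotation -------------------------------------------------------------

def read_annotation(path: str | Path) -> GeneAnnotation:
    frame = pd.read_csv(
        path,
        sep="\t",
        names=["gene_id", "class", "chrom", "start", "end", "strand", "cytoband"],
        header=0,
    )
    return GeneAnnotation.from_frame(frame)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


# -- binary profile ---------------------------------------------------------

def write_profile(profile: BinaryAlterationProfile, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    profile.matrix.to_csv(matrix_path, sep="\t", index_label="sample_id")
    side = pd.DataFrame(
        {
            "gene_id": profile.genes,
            "class": profile.gene_class.values,
            "sign": profile.alteration_sign.values,
            "gamma": profile.gamma.values,
        }
    )
    side.to_csv(sidecar_path, sep="\t", index=False)


def read_profile(matrix_path: str | Path, sidecar_path: str | Path) -> BinaryAlterationProfile:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0).astype("int8")
    side = pd.read_csv(sidecar_path, sep="\t").set_index("gene_id")
    side = side.loc[list(mat.columns)]
    return BinaryAlterationProfile(mat, side["sign"].rename("sign"), side["class"].rename("class"))


# -- gene sets --------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> member ids..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = NA) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_hallmark_termsets(path: str | Path) -> list[HallmarkTermSet]:
    """Curated hallmark -> GO-term GMT."""
    return [
        HallmarkTermSet(name, set(terms), {t: "curated" for t in terms})
        for name, terms in read_gmt(path).items()
    ]


def write_hallmark_termsets(sets: list[HallmarkTermSet], path: str | Path) -> None:
    write_gmt({s.hallmark: s.terms for s in sets}, path)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line (e.g. a known-driver catalog)."""
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


# -- ontology ---------------------------------------------------------------

def read_obo(path: str | Path, annotations: Mapping[str, set[str]] | None = None) -> GoDag:
    """Load an OBO 1.2 file, keeping only is_a links."""
    graph = obonet.read_obo(str(path))
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]
    return GoDag(edges, terms=list(graph.nodes), annotations=annotations)


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialise the is_a DAG as minimal OBO 1.2."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.graph.nodes):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")


def read_gene_annotations(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (gene_id, term_id) -> gene -> term set."""
    frame = pd.read_csv(path, sep="\t", names=["gene_id", "term_id"], header=0)
    out: dict[str, set[str]] = {}
    for row in frame.itertuples():
        out.setdefault(str(row.gene_id), set()).add(str(row.term_id))
    return out


def write_gene_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


# -- networks and modules ---------------------------------------------------

def write_network(network: MexNetwork, path: str | Path) -> None:
    rows = [
        (e.gene_a, e.gene_b, e.p_value, e.rule, e.overlap) for e in network.edges
    ]
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "p", "rule", "overlap"])
    frame.sort_values(["gene_a", "gene_b"], kind="mergesort").to_csv(path, sep="\t", index=False)


def modules_frame(modules: list[Module], module_ids: list[str] | None = None) -> pd.DataFrame:
    ids = module_ids or [f"M{i + 1}" for i in range(len(modules))]
    rows = []
    for mid, mod in zip(ids, modules):
        rows.append(
            (
                mid,
                mod.hallmark,
                ";".join(mod.sorted_members()),
                mod.f_score,
                mod.coverage,
                mod.p_empirical if mod.p_empirical is not None else NA,
                mod.p_adjusted if mod.p_adjusted is not None else NA,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["module_id", "hallmark", "members", "f_score", "coverage", "p_empirical", "p_adjusted"],
    )


def write_modules(modules: list[Module], path: str | Path, module_ids: list[str] | None = None) -> None:
    modules_frame(modules, module_ids).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
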