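"""Cell-ontology annotation-granularity alignment.

Datasets annotated at different depths of the Cell Ontology cannot be
compared cell type by cell type. The aligner works on the ``is_a`` DAG
only: it first *trims* each dataset (any term whose strict ancestor is also
used in the same dataset collapses onto that ancestor), then *matches*
across datasets by collapsing every used term that has a strict ancestor
anywhere in the pooled term set onto its nearest pooled ancestor, iterated
to a fixed point. The final aligned terms form an antichain — no aligned
term is an ancestor of another — at the finest granularity the collapse
rule permits; terms with no ancestry relation to any other dataset's terms
are preserved, so dataset-specific cell types survive alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import networkx as nx
import obonet

from xassess.errors import FormatError, ValidationError


@dataclass
class OntologyDAG:
    """Ontology terms with ``is_a`` edges (child → parent)."""

    graph: nx.DiGraph  # edges point child -> parent
    names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph


@dataclass
class AnnotationMatching:
    """Per-dataset original-term → aligned-term maps and the final term set."""

    per_dataset: list[dict[str, str]]
    aligned_terms: set[str]


def load_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO ontology keeping only ``is_a`` edges.

    Obsolete terms are dropped (obonet default); other relationship types
    (part_of, develops_from, …) are ignored. A cycle among is_a edges is a
    format error — ontologies must be acyclic.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node)
        if "name" in data:
            names[node] = data["name"]
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in multigraph.nodes:
            raise FormatError(f"is_a edge {child} -> {parent} targets an unknown term")
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise FormatError(f"is_a cycle detected in {path}: {cycle}")
    return OntologyDAG(graph=graph, names=names)


def strict_ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """All terms reachable from `term` by following ``is_a`` upward, excluding itself."""
    if term not in dag:
        raise KeyError(f"unknown ontology term {term!r}")
    # edges point child -> parent, so graph-descendants are ontology ancestors
    return set(nx.descendants(dag.graph, term))


def _nearest_present(dag: OntologyDAG, term: str, present: set[str]) -> str | None:
    """Nearest strict ancestor of `term` within `present`.

    Ties on is_a path length break by ascending term id, for determinism.
    """
    lengths = nx.single_source_shortest_path_length(dag.graph, term)
    candidates = [
        (dist, anc) for anc, dist in lengths.items() if anc != term and anc in present
    ]
    if not candidates:
        return None
    return min(candidates)[1]


def _collapse_to_fixpoint(dag: OntologyDAG, terms: Iterable[str]) -> dict[str, str]:
    """Iteratively map every term with a present strict ancestor onto it.

    Returns the composed original → final map over the input term set. At
    the fixed point the surviving terms are exactly those with no strict
    ancestor in the input set (an antichain).
    """
    current = {t: t for t in set(terms)}
    while True:
        present = set(current.values())
        changed = False
        for origin, term in current.items():
            target = _nearest_present(dag, term, present)
            if target is not None:
                current[origin] = target
                changed = True
        if not changed:
            return current


def trim_dataset_terms(dag: OntologyDAG, terms: Sequence[str]) -> dict[str, str]:
    """Remove within-dataset redundancy: descendants collapse onto present ancestors.

    Returns a map over the distinct input terms; the image has no internal
    ancestry (e.g. ``{"inhibitory neuron", "neuron"}`` maps the former onto
    the latter).
    """
    unknown = sorted(set(terms) - dag.terms)
    if unknown:
        raise ValidationError(f"terms absent from the ontology: {unknown}")
    return _collapse_to_fixpoint(dag, terms)


def match_ontology_sets(
    dag: OntologyDAG, term_sets: Sequence[Iterable[str]]
) -> AnnotationMatching:
    """Align annotation granularity across datasets.

    Each dataset's terms are trimmed, then the pooled union is collapsed to
    its fixed point: a term used anywhere that has a strict ancestor used
    anywhere (including in another dataset) is mapped onto that nearest
    ancestor — the descendant-to-ancestor matching that yields the last
    common ancestor across datasets. Terms unrelated to every other term
    survive unchanged.
    """
    trimmed = [trim_dataset_terms(dag, list(ts)) for ts in term_sets]
    union = {t for m in trimmed for t in m.values()}
    collapsed = _collapse_to_fixpoint(dag, union)
    per_dataset = [
        {origin: collapsed[mid] for origin, mid in m.items()} for m in trimmed
    ]
    aligned = {collapsed[mid] for m in trimmed for mid in m.values()}
    return AnnotationMatching(per_dataset=per_dataset, aligned_terms=aligned)


def apply_matching(
    adata: ad.AnnData,
    mapping: Mapping[str, str],
    celltype_key: str = "cell_type",
) -> ad.AnnData:
    """Rewrite a dataset's cell-type column through an alignment map.

    Counts are untouched; the original labels are kept in
    ``<celltype_key>_original``. Every observed term must have a mapping
    entry (identity entries included).
    """
    observed = set(map(str, adata.obs[celltype_key]))
    unmapped = sorted(observed - set(mapping))
    if unmapped:
        raise ValidationError(f"terms with no matching entry: {unmapped}")
    out = adata.copy()
    provenance = f"{celltype_key}_original"
    if provenance not in out.obs:
        out.obs[provenance] = out.obs[celltype_key].astype(str)
    out.obs[celltype_key] = [mapping[t] for t in map(str, out.obs[celltype_key])]
    return out


def write_matching_tsv(matching: AnnotationMatching, out_dir: str | Path) -> list[Path]:
    """Export per-dataset (original_term, aligned_term) two-column TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mapping in enumerate(matching.per_dataset):
        path = out_dir / f"matching_dataset{i}.tsv"
        with open(path, "w") as fh:
            fh.write("original_term\taligned_term\n")
            for origin in sorted(mapping):
                fh.write(f"{origin}\t{mapping[origin]}\n")
        paths.append(path)
    return paths
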