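"""Cross-species gene-group construction and count-matrix concatenation.

Genes from different species are joined into *gene groups* — connected
components of the pairwise ortholog graph supplied as a homology table.
Raw counts from every species are then concatenated column-by-column under
one of three matching strategies:

``O2O``
    only groups with exactly one gene per species (strict one-to-one
    orthologs);
``HE``
    additionally include one-to-many / many-to-many groups, representing
    each species by the paralog with the *higher mean expression* in that
    species;
``SH``
    as ``HE`` but the representative is the paralog with the *stronger
    homology confidence*, compared lexicographically on ENSEMBL-style
    attributes (orthology confidence, gene-order conservation score,
    whole-genome-alignment coverage, query/target percent identity).

Counts are never normalised here: every output column carries the selected
source gene's raw counts unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from xassess.errors import FormatError, ValidationError

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")

#: ENSEMBL/biomaRt spellings accepted for the homology_type column.
HOMOLOGY_TYPE_DIALECT: dict[str, str] = {
    "one2one": "one2one",
    "one2many": "one2many",
    "many2many": "many2many",
    "ortholog_one2one": "one2one",
    "ortholog_one2many": "one2many",
    "ortholog_many2many": "many2many",
    "1:1": "one2one",
    "1:many": "one2many",
    "many:many": "many2many",
}

REQUIRED_COLUMNS = ("species_a", "gene_a", "species_b", "gene_b", "homology_type")

#: Confidence attributes in decreasing priority for SH selection.
ATTRIBUTE_COLUMNS = (
    "orthology_confidence",
    "goc_score",
    "wga_coverage",
    "query_identical",
    "target_identical",
)


@dataclass(frozen=True)
class HomologyRecord:
    """One pairwise ortholog relation between genes of two species."""

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    homology_type: str
    orthology_confidence: float | None = None
    goc_score: float | None = None
    wga_coverage: float | None = None
    query_identical: float | None = None
    target_identical: float | None = None

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValidationError(
                f"homology record links {self.gene_a!r} and {self.gene_b!r} "
                f"within one species ({self.species_a!r})"
            )
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValidationError(f"unknown homology type {self.homology_type!r}")

    def attributes(self) -> tuple[float | None, ...]:
        return (
            self.orthology_confidence,
            self.goc_score,
            self.wga_coverage,
            self.query_identical,
            self.target_identical,
        )


@dataclass
class GeneGroup:
    """A cross-species gene group (connected component of the ortholog graph)."""

    members: dict[str, list[str]]  # species -> sorted gene ids
    group_type: str  # "O2O" | "O2M_M2M" | "species_specific"
    usable: bool
    group_id: str = ""

    def genes(self) -> Iterable[tuple[str, str]]:
        for species in sorted(self.members):
            for gene in self.members[species]:
                yield species, gene


@dataclass
class GeneGroupSet:
    """All gene groups for a set of studied species, plus the source records."""

    groups: list[GeneGroup]
    species: list[str]
    records: list[HomologyRecord] = field(default_factory=list)

    def usable_groups(self, types: Sequence[str]) -> list[GeneGroup]:
        return [g for g in self.groups if g.usable and g.group_type in types]


def _parse_optional_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "NA", "NaN", "nan"):
            return None
    return float(value)


def parse_homology_table(path: str | Path, species: Sequence[str]) -> list[HomologyRecord]:
    """Read a pairwise homology TSV restricted to the studied species.

    The file must carry at least the columns ``species_a, gene_a, species_b,
    gene_b, homology_type``; the five ENSEMBL confidence attribute columns
    are optional and may contain missing values. ENSEMBL dialect spellings
    of the homology type (``ortholog_one2one`` …) are normalised.

    Rows whose species pair is not fully contained in ``species`` are
    dropped. Malformed rows raise :class:`FormatError` with their 1-based
    row numbers.
    """
    species = list(species)
    if len(set(species)) != len(species):
        raise ValidationError(f"duplicate species ids in {species}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"homology table {path} is missing columns: {missing}")

    records: list[HomologyRecord] = []
    bad_rows: list[str] = []
    seen_species: set[str] = set()
    wanted = set(species)
    for idx, row in table.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        sp_a, sp_b = row["species_a"], row["species_b"]
        if pd.isna(sp_a) or pd.isna(sp_b) or pd.isna(row["gene_a"]) or pd.isna(row["gene_b"]):
            bad_rows.append(f"row {rownum}: missing species or gene id")
            continue
        seen_species.update((sp_a, sp_b))
        if sp_a not in wanted or sp_b not in wanted:
            continue
        raw_type = str(row["homology_type"]).strip()
        homology_type = HOMOLOGY_TYPE_DIALECT.get(raw_type.lower())
        if homology_type is None:
            bad_rows.append(f"row {rownum}: unrecognised homology_type {raw_type!r}")
            continue
        attrs = {
            col: _parse_optional_float(row[col]) if col in table.columns else None
            for col in ATTRIBUTE_COLUMNS
        }
        try:
            records.append(
                HomologyRecord(
                    species_a=str(sp_a),
                    gene_a=str(row["gene_a"]),
                    species_b=str(sp_b),
                    gene_b=str(row["gene_b"]),
                    homology_type=homology_type,
                    **attrs,
                )
            )
        except ValidationError as exc:
            bad_rows.append(f"row {rownum}: {exc}")
    if bad_rows:
        raise FormatError(
            f"homology table {path} has malformed rows:\n" + "\n".join(bad_rows)
        )
    if len(table) and not seen_species & wanted:
        raise ValidationError(
            f"none of the studied species {sorted(wanted)} appear in {path} "
            f"(table species: {sorted(seen_species)})"
        )
    return records


def _component_sort_key(members: Mapping[str, list[str]]) -> tuple:
    return tuple(sorted((s, g) for s in members for g in members[s]))


def build_gene_groups(
    records: Sequence[HomologyRecord],
    matrices: Mapping[str, ad.AnnData],
) -> GeneGroupSet:
    """Group genes across species from pairwise ortholog records.

    Groups are the connected components of the undirected gene–gene graph
    over all records; a quantified gene that appears in no record forms a
    ``species_specific`` singleton group. A group is *usable* for
    cross-species concatenation iff it has at least one gene in every
    studied species and every member gene is quantified in its species'
    matrix. Output ordering is canonical (independent of record order).
    """
    species = list(matrices)
    for sp_id, adata in matrices.items():
        if adata.var_names.has_duplicates:
            raise ValidationError(f"matrix for species {sp_id!r} has duplicate gene ids")

    graph: nx.Graph = nx.Graph()
    for rec in records:
        graph.add_edge((rec.species_a, rec.gene_a), (rec.species_b, rec.gene_b))

    quantified = {sp_id: set(map(str, m.var_names)) for sp_id, m in matrices.items()}

    groups: list[GeneGroup] = []
    for component in nx.connected_components(graph):
        members: dict[str, list[str]] = {}
        for sp_id, gene in component:
            members.setdefault(sp_id, []).append(gene)
        for genes in members.values():
            genes.sort()
        is_o2o = all(len(g) == 1 for g in members.values())
        usable = set(members) == set(species) and all(
            gene in quantified.get(sp_id, set())
            for sp_id, genes in members.items()
            for gene in genes
        )
        groups.append(
            GeneGroup(
                members=members,
                group_type="O2O" if is_o2o else "O2M_M2M",
                usable=usable,
            )
        )

    in_records = set(graph.nodes)
    for sp_id in species:
        for gene in map(str, matrices[sp_id].var_names):
            if (sp_id, gene) not in in_records:
                groups.append(
                    GeneGroup(
                        members={sp_id: [gene]},
                        group_type="species_specific",
                        usable=False,
                    )
                )

    groups.sort(key=lambda g: _component_sort_key(g.members))
    for i, group in enumerate(groups):
        group.group_id = f"group{i:05d}"
    return GeneGroupSet(groups=groups, species=species, records=list(records))


def _counts_column(adata: ad.AnnData, gene: str) -> np.ndarray:
    idx = adata.var_names.get_indexer([gene])
    if idx[0] < 0:
        raise KeyError(f"gene {gene!r} not found in matrix")
    col = adata.X[:, idx[0]]
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col).ravel()


def mean_expression(adata: ad.AnnData, gene: str) -> float:
    """Arithmetic mean of a gene's raw counts over all cells (zeros included)."""
    return float(_counts_column(adata, gene).mean())


def _gene_attribute_vector(
    gene: str, species: str, records: Sequence[HomologyRecord]
) -> tuple[float, ...]:
    """Element-wise best confidence attributes over the records linking `gene`.

    Missing attributes rank lowest (-inf), so a gene with any recorded value
    for an attribute beats one with none.
    """
    best = [-math.inf] * len(ATTRIBUTE_COLUMNS)
    for rec in records:
        if (rec.species_a, rec.gene_a) == (species, gene) or (
            rec.species_b,
            rec.gene_b,
        ) == (species, gene):
            for i, value in enumerate(rec.attributes()):
                if value is not None and value > best[i]:
                    best[i] = value
    return tuple(best)


def _select_representative(
    group: GeneGroup,
    species: str,
    matrices: Mapping[str, ad.AnnData],
    records: Sequence[HomologyRecord],
    method: str,
) -> str:
    genes = group.members[species]
    if len(genes) == 1:
        return genes[0]
    if method == "HE":
        # max mean expression; ties by ascending gene id (genes pre-sorted)
        means = [mean_expression(matrices[species], g) for g in genes]
        return genes[int(np.argmax(means))]
    # SH: lexicographic on the attribute vector, higher is better
    group_genes = set(group.genes())
    relevant = [
        r
        for r in records
        if (r.species_a, r.gene_a) in group_genes and (r.species_b, r.gene_b) in group_genes
    ]
    vectors = [_gene_attribute_vector(g, species, relevant) for g in genes]
    # strongest attribute vector; residual ties break by ascending gene id
    best = min(
        range(len(genes)),
        key=lambda i: (tuple(-v for v in vectors[i]), genes[i]),
    )
    return genes[best]


def concat_counts(
    matrices: Mapping[str, ad.AnnData],
    groups: GeneGroupSet,
    method: str,
) -> ad.AnnData:
    """Concatenate per-species raw counts into a cells × gene-groups matrix.

    ``method`` selects the strategy: ``"O2O"`` keeps strict one-to-one
    groups only; ``"HE"`` / ``"SH"`` add one-to-many / many-to-many groups
    with paralogs matched by higher expression or stronger homology. Cell
    metadata is concatenated unchanged; counts are carried over exactly.
    """
    method = method.upper()
    if method not in ("O2O", "HE", "SH"):
        raise ValidationError(f"unknown concatenation method {method!r}")
    if method == "O2O":
        selected_groups = groups.usable_groups(["O2O"])
    else:
        selected_groups = groups.usable_groups(["O2O", "O2M_M2M"])
    if not selected_groups:
        raise ValidationError(f"no usable gene groups for method {method}")

    species_order = groups.species
    all_names = pd.Index(
        np.concatenate([np.asarray(matrices[s].obs_names, dtype=object) for s in species_order])
    )
    if all_names.has_duplicates:
        dupes = all_names[all_names.duplicated()].unique()[:5].tolist()
        raise ValidationError(f"duplicate cell ids across species, e.g. {dupes}")

    selection: dict[str, list[str]] = {}
    for sp_id in species_order:
        selection[sp_id] = [
            _select_representative(g, sp_id, matrices, groups.records, method)
            for g in selected_groups
        ]

    blocks = []
    obs_frames = []
    for sp_id in species_order:
        adata = matrices[sp_id]
        idx = adata.var_names.get_indexer(selection[sp_id])
        if (idx < 0).any():
            bad = [g for g, i in zip(selection[sp_id], idx) if i < 0]
            raise ValidationError(f"selected genes missing from {sp_id!r} matrix: {bad[:5]}")
        block = adata.X[:, idx]
        blocks.append(sp.csr_matrix(block) if sp.issparse(adata.X) else np.asarray(block))
        obs_frames.append(adata.obs.copy())

    sparse_any = any(sp.issparse(b) for b in blocks)
    if sparse_any:
        X = sp.vstack([sp.csr_matrix(b) for b in blocks], format="csr")
    else:
        X = np.vstack(blocks)

    obs = pd.concat(obs_frames, axis=0)
    obs.index = all_names
    var = pd.DataFrame(index=[g.group_id for g in selected_groups])
    var["group_type"] = [g.group_type for g in selected_groups]
    var["homology_method"] = method
    for sp_id in species_order:
        var[f"gene_{sp_id}"] = selection[sp_id]
    out = ad.AnnData(X=X, obs=obs, var=var)
    out.uns["homology_method"] = method
    return out


def export_unshared_features(
    matrices: Mapping[str, ad.AnnData],
    groups: GeneGroupSet,
) -> dict[str, ad.AnnData]:
    """Per-species submatrices of species-specific (no-homology) genes.

    These are the unshared features some integration methods consume in
    addition to the homology-matched columns; they are disjoint from every
    shared gene group by construction.
    """
    specific: dict[str, set[str]] = {sp_id: set() for sp_id in groups.species}
    for group in groups.groups:
        if group.group_type == "species_specific":
            (sp_id,) = group.members
            specific[sp_id].update(group.members[sp_id])
    out = {}
    for sp_id, adata in matrices.items():
        keep = [g for g in map(str, adata.var_names) if g in specific.get(sp_id, set())]
        out[sp_id] = adata[:, keep].copy()
    return out
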