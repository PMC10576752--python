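"""Shared fixtures: small synthetic datasets and toy ontology builders."""

from __future__ import annotations

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from xassess.homology import build_gene_groups, concat_counts, parse_homology_table
from xassess.metrics import standard_reduce
from xassess.ontology import OntologyDAG
from xassess.simulate import SimulationConfig, simulate_multispecies


def make_adata(counts, genes, species, celltypes=None, batch=None, prefix=None):
    """Small annotated count matrix for hand-built fixtures."""
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.shape[0]
    prefix = prefix or species
    obs = pd.DataFrame(
        {
            "species": species,
            "batch": batch if batch is not None else species,
            "cell_type": celltypes if celltypes is not None else "typeA",
        },
        index=[f"{prefix}_c{i}" for i in range(n)],
    )
    return ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=list(genes)))


def random_dag(rng: np.random.Generator, n_terms: int, max_parents: int = 2) -> OntologyDAG:
    """Random is_a DAG: term i may take parents among terms < i."""
    graph = nx.DiGraph()
    terms = [f"T{i:02d}" for i in range(n_terms)]
    graph.add_nodes_from(terms)
    for i in range(1, n_terms):
        n_parents = int(rng.integers(0, max_parents + 1))
        if n_parents:
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                graph.add_edge(terms[i], terms[int(p)])
    return OntologyDAG(graph=graph, names={t: t for t in terms})


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic two-species dataset (seed 1)."""
    return simulate_multispecies(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def homology_records(dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("homology") / "homology.tsv"
    dataset.homology.to_csv(path, sep="\t", index=False)
    return parse_homology_table(path, dataset.species)


@pytest.fixture(scope="session")
def gene_groups(dataset, homology_records):
    return build_gene_groups(homology_records, dataset.matrices)


@pytest.fixture(scope="session")
def concat_o2o(dataset, gene_groups):
    return concat_counts(dataset.matrices, gene_groups, "O2O")


@pytest.fixture(scope="session")
def pre_rep(concat_o2o):
    """Unintegrated reference embedding of the O2O concatenation."""
    return standard_reduce(concat_o2o, batch_key="species")[:, :20]
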