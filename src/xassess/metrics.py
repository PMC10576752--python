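"""Raw assessment metrics for cross-species integration outputs.

An integration output is one of three kinds — a latent embedding, a
corrected pseudo-count matrix, or a k-NN graph — and each metric declares
which kinds it applies to. Embedding-based metrics (PCR, bASW, cASW, kBET)
raise :class:`MetricNotApplicableError` on graph-only outputs, matching the
exclusion of graph-output methods from score-based ranking; graph metrics
(graph connectivity, NMI, isolated-label F1, alignment score) run on every
kind, building the k-NN graph on the fly where needed.

Conventions follow the standard single-cell workflow: k = 20 neighbours on
the first 20 dimensions of the embedding (or the PCA of a corrected
matrix), Euclidean distances, silhouettes on the same 20 dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.stats import chisquare
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)

from xassess.errors import MetricNotApplicableError, ValidationError

BATCH_METRICS = ("PCR", "bASW", "GC", "kBET")
BIO_METRICS = ("cASW", "NMI", "ARI", "isoF1")

#: resolution sweep used for the NMI / isolated-label clustering search
NMI_RESOLUTIONS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 1))


@dataclass
class NeighborGraph:
    """Boolean k-NN adjacency (no self-edges, per-row degree ≤ k)."""

    adjacency: sp.csr_matrix
    k: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class IntegrationOutput:
    """An integration result to assess, with its cell metadata.

    ``kind`` is one of ``embedding`` (cells × dims latent coordinates),
    ``corrected_matrix`` (cells × genes pseudo-counts) or ``knn_graph``
    (cells × cells sparse adjacency). ``strategy`` labels the
    algorithm × homology-method combination that produced it.
    """

    kind: str
    data: np.ndarray | sp.spmatrix
    strategy: str
    cell_meta: pd.DataFrame
    _rep_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("embedding", "corrected_matrix", "knn_graph"):
            raise ValidationError(f"unknown integration output kind {self.kind!r}")
        if self.data.shape[0] != len(self.cell_meta):
            raise ValidationError(
                f"{self.data.shape[0]} data rows vs {len(self.cell_meta)} metadata rows"
            )

    def representation(self, n_dims: int = 20) -> np.ndarray:
        """Dense cells × n_dims coordinates for embedding-based metrics.

        Embeddings are truncated to their first ``n_dims`` columns; a
        corrected matrix is scaled (unit variance, clipped at 10) and
        projected onto ``n_dims`` principal components. Graph-only outputs
        have no representation.
        """
        if self.kind == "knn_graph":
            raise MetricNotApplicableError(
                f"strategy {self.strategy!r} outputs a k-NN graph only"
            )
        key = ("rep", n_dims)
        if key not in self._rep_cache:
            X = self.data.toarray() if sp.issparse(self.data) else np.asarray(self.data)
            X = X.astype(np.float64)
            if self.kind == "embedding":
                rep = X[:, : min(n_dims, X.shape[1])]
            else:
                rep = _scale_pca(X, n_comps=min(n_dims, X.shape[0] - 1, X.shape[1] - 1))
            self._rep_cache[key] = rep
        return self._rep_cache[key]

    def neighbor_graph(self, k: int = 20, n_dims: int = 20) -> NeighborGraph:
        if self.kind == "knn_graph":
            adj = sp.csr_matrix(self.data).astype(bool)
            adj.setdiag(False)
            adj.eliminate_zeros()
            degree = int(adj.sum(axis=1).max()) if adj.nnz else 0
            return NeighborGraph(adjacency=adj, k=max(degree, 1))
        key = ("graph", k, n_dims)
        if key not in self._rep_cache:
            self._rep_cache[key] = knn_graph(self.representation(n_dims), k=k, n_dims=n_dims)
        return self._rep_cache[key]


def _scale_pca(X: np.ndarray, n_comps: int) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    return PCA(n_components=n_comps, svd_solver="full", random_state=0).fit_transform(Z)


def standard_reduce(
    adata: ad.AnnData,
    batch_key: str | None = None,
    n_comps: int = 40,
    return_hvg: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[str]]:
    """Standard scRNA-seq reduction of a raw count matrix to a PCA embedding.

    Total-count normalisation, log1p, dispersion-based HVG selection
    (min_mean 0.0125, max_mean 3, min_disp 0.5; with ``batch_key`` the
    per-batch HVG sets are intersected), unit-variance scaling clipped at
    10, PCA. Returns the cells × n_comps embedding.
    """
    work = adata.copy()
    work.X = work.X.astype(np.float64)
    sc.pp.normalize_total(work, target_sum=1e4)
    sc.pp.log1p(work)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            work, min_mean=0.0125, max_mean=3, min_disp=0.5, batch_key=batch_key
        )
    if batch_key is not None and "highly_variable_intersection" in work.var:
        mask = work.var["highly_variable_intersection"].to_numpy()
    else:
        mask = work.var["highly_variable"].to_numpy()
    if int(mask.sum()) < 2:
        raise ValidationError(
            f"only {int(mask.sum())} highly variable genes survive"
            + (" the cross-batch intersection" if batch_key else "")
        )
    work = work[:, mask].copy()
    hvg_names = list(map(str, work.var_names))
    sc.pp.scale(work, max_value=10)
    n_comps = min(n_comps, work.n_obs - 1, work.n_vars - 1)
    sc.tl.pca(work, svd_solver="arpack", n_comps=n_comps)
    embedding = np.asarray(work.obsm["X_pca"], dtype=np.float64)
    if return_hvg:
        return embedding, hvg_names
    return embedding


def knn_graph(rep: np.ndarray, k: int = 20, n_dims: int = 20) -> NeighborGraph:
    """Euclidean k-NN graph on the first ``n_dims`` dimensions.

    No self-edges; distance ties break by ascending cell index so the graph
    is deterministic for duplicated coordinates.
    """
    rep = np.asarray(rep, dtype=np.float64)
    n = rep.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n})")
    X = rep[:, : min(n_dims, rep.shape[1])]
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    sq = (X**2).sum(axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2 * X[start:stop] @ X.T + sq[None, :]
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        cols[start * k : stop * k] = order.ravel()
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=bool), (rows, cols)), shape=(n, n)
    )
    return NeighborGraph(adjacency=adj, k=k)


def alignment_score(graph: NeighborGraph, species: Sequence[str]) -> float:
    """Mean fraction of attainable cross-species neighbours per cell.

    For each cell, the number of neighbours from another species divided by
    the maximum possible — min(k, number of cells of other species) — then
    averaged over all cells. 1 means every attainable neighbour slot is
    cross-species; 0 means none are.
    """
    labels = np.asarray(species, dtype=object)
    codes, counts = np.unique(labels, return_counts=True)
    if len(codes) < 2:
        raise MetricNotApplicableError("alignment score needs at least two species")
    n = graph.n_cells
    count_of = dict(zip(codes, counts))
    n_other = np.array([n - count_of[s] for s in labels])
    adj = graph.adjacency.tocsr()
    cross = np.zeros(n)
    for i in range(n):
        nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        cross[i] = np.sum(labels[nbrs] != labels[i])
    denom = np.minimum(graph.k, n_other)
    return float(np.mean(cross / denom))


def _variance_explained_by(rep: np.ndarray, covariate: Sequence) -> float:
    """PC-variance-weighted R² of the covariate across principal components."""
    rep = np.asarray(rep, dtype=np.float64)
    n_comps = min(rep.shape[0] - 1, rep.shape[1])
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=0).fit(rep)
    pcs = pca.transform(rep)
    lam = pca.explained_variance_
    labels = np.asarray(covariate, dtype=object)
    groups = [labels == g for g in np.unique(labels)]
    r2 = np.zeros(n_comps)
    for j in range(n_comps):
        y = pcs[:, j]
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot <= 0:
            continue
        ss_res = sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups)
        r2[j] = 1 - ss_res / ss_tot
    total = lam.sum()
    if total <= 0:
        return 0.0
    return float((lam * r2).sum() / total)


def principal_component_regression(
    pre_rep: np.ndarray, post_rep: np.ndarray, covariate: Sequence
) -> float:
    """Reduction in covariate-explained variance from pre- to post-integration.

    Var_expl(rep) = Σ_j λ_j·R²_j / Σ_j λ_j over the principal components of
    ``rep``, with R²_j from regressing PC j on the one-hot covariate; the
    score is clip((pre − post) / pre, 0, 1).
    """
    if len(pre_rep) != len(post_rep):
        raise ValidationError("pre and post representations must cover the same cells")
    pre = _variance_explained_by(pre_rep, covariate)
    if pre <= 1e-12:
        raise MetricNotApplicableError(
            "covariate explains no variance in the unintegrated reference"
        )
    post = _variance_explained_by(post_rep, covariate)
    return float(np.clip((pre - post) / pre, 0.0, 1.0))


def batch_asw(
    rep: np.ndarray, batch: Sequence, celltype: Sequence, n_dims: int = 20
) -> float:
    """Batch-mixing silhouette: mean of 1 − |silhouette(batch)| per cell type.

    Cell types observed in a single batch are excluded; the per-type means
    are averaged without size weighting.
    """
    X = np.asarray(rep, dtype=np.float64)[:, :n_dims]
    batch = np.asarray(batch, dtype=object)
    celltype = np.asarray(celltype, dtype=object)
    per_type = []
    for ct in np.unique(celltype):
        mask = celltype == ct
        batches = np.unique(batch[mask])
        if len(batches) < 2 or mask.sum() <= len(batches):
            continue
        s = silhouette_samples(X[mask], batch[mask])
        per_type.append(float(np.mean(1 - np.abs(s))))
    if not per_type:
        raise MetricNotApplicableError("no cell type spans at least two batches")
    return float(np.mean(per_type))


def celltype_asw(rep: np.ndarray, celltype: Sequence, n_dims: int = 20) -> float:
    """Cell-type silhouette rescaled to [0, 1]: (mean silhouette + 1) / 2."""
    X = np.asarray(rep, dtype=np.float64)[:, :n_dims]
    celltype = np.asarray(celltype, dtype=object)
    if len(np.unique(celltype)) < 2:
        raise MetricNotApplicableError("cell-type silhouette needs at least two cell types")
    return float((silhouette_score(X, celltype) + 1) / 2)


def graph_connectivity(graph: NeighborGraph, celltype: Sequence) -> float:
    """Mean, over cell types, of the largest-connected-component fraction.

    The k-NN adjacency is symmetrised; for each cell type the subgraph its
    cells induce should ideally be one connected component (value 1).
    """
    celltype = np.asarray(celltype, dtype=object)
    adj = graph.adjacency.maximum(graph.adjacency.T).tocsr()
    scores = []
    for ct in np.unique(celltype):
        idx = np.flatnonzero(celltype == ct)
        sub = adj[idx][:, idx]
        n_comp, labels = sp.csgraph.connected_components(sub, directed=False)
        largest = np.bincount(labels).max()
        scores.append(largest / len(idx))
    return float(np.mean(scores))


def kbet_acceptance(
    rep_or_graph: np.ndarray | NeighborGraph,
    batch: Sequence,
    celltype: Sequence,
    alpha: float = 0.05,
    k: int = 20,
    subsample: int = 500,
    seed: int = 0,
) -> float:
    """Chi-squared k-NN batch-composition acceptance rate.

    A simplified kBET: per cell type, each (sub-sampled, at most
    ``subsample`` cells, fixed seed) cell's neighbourhood batch composition
    is tested by a chi-squared goodness-of-fit against that cell type's
    global batch proportions; the acceptance rate is the fraction of cells
    with p > alpha, averaged over cell types. No parity with the reference
    kBET implementation is claimed.
    """
    batch = np.asarray(batch, dtype=object)
    celltype = np.asarray(celltype, dtype=object)
    if len(np.unique(batch)) < 2:
        raise MetricNotApplicableError("kBET needs at least two batches")
    rng = np.random.default_rng(seed)
    rates = []
    for ct in np.unique(celltype):
        idx = np.flatnonzero(celltype == ct)
        batches_ct, counts_ct = np.unique(batch[idx], return_counts=True)
        if len(batches_ct) < 2 or len(idx) < 3:
            continue
        props = counts_ct / counts_ct.sum()
        k_eff = min(k, len(idx) - 1)
        if isinstance(rep_or_graph, NeighborGraph):
            adj = rep_or_graph.adjacency.tocsr()
            neighbor_lists = []
            in_type = np.zeros(adj.shape[0], dtype=bool)
            in_type[idx] = True
            for i in idx:
                nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
                neighbor_lists.append(nbrs[in_type[nbrs]])
        else:
            sub_graph = knn_graph(np.asarray(rep_or_graph)[idx], k=k_eff, n_dims=20)
            adj = sub_graph.adjacency
            neighbor_lists = [
                idx[adj.indices[adj.indptr[r] : adj.indptr[r + 1]]]
                for r in range(len(idx))
            ]
        order = np.arange(len(idx))
        if len(idx) > subsample:
            order = np.sort(rng.choice(len(idx), size=subsample, replace=False))
        accepted = 0
        tested = 0
        batch_code = {b: j for j, b in enumerate(batches_ct)}
        for r in order:
            nbrs = neighbor_lists[r]
            if len(nbrs) == 0:
                continue
            observed = np.zeros(len(batches_ct))
            for b in batch[nbrs]:
                observed[batch_code[b]] += 1
            expected = props * observed.sum()
            keep = expected > 0
            stat = chisquare(observed[keep], expected[keep])
            tested += 1
            if stat.pvalue > alpha:
                accepted += 1
        if tested:
            rates.append(accepted / tested)
    if not rates:
        raise MetricNotApplicableError("no cell type qualifies for kBET")
    return float(np.mean(rates))


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings (≤ 1, can be negative)."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def _leiden_sweep(
    graph: NeighborGraph, resolutions: Sequence[float], seed: int
) -> list[np.ndarray]:
    """Modularity-style (RB-configuration) Leiden partitions over a resolution sweep."""
    adj = graph.adjacency.maximum(graph.adjacency.T).tocoo()
    mask = adj.row < adj.col
    edges = list(zip(adj.row[mask].tolist(), adj.col[mask].tolist()))
    g = igraph.Graph(n=graph.n_cells, edges=edges, directed=False)
    partitions = []
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res),
            seed=seed,
            n_iterations=2,
        )
        partitions.append(np.asarray(part.membership))
    return partitions


def optimized_nmi(
    graph: NeighborGraph,
    celltype: Sequence,
    seed: int = 0,
    partitions: list[np.ndarray] | None = None,
) -> float:
    """NMI between cell types and the best clustering over a resolution sweep.

    Leiden community detection at resolutions 0.1–2.0 (step 0.1); reports
    the maximum arithmetic-normalised mutual information against the
    cell-type labels. A constant cell-type labeling scores 0 by convention
    (zero entropy carries no information to recover).
    """
    celltype = np.asarray(celltype, dtype=object)
    if len(np.unique(celltype)) < 2:
        return 0.0
    if partitions is None:
        partitions = _leiden_sweep(graph, NMI_RESOLUTIONS, seed)
    best = 0.0
    for membership in partitions:
        score = normalized_mutual_info_score(
            celltype, membership, average_method="arithmetic"
        )
        best = max(best, float(score))
    return best


def isolated_label_f1(
    celltype: Sequence,
    batch: Sequence,
    graph: NeighborGraph,
    seed: int = 0,
    partitions: list[np.ndarray] | None = None,
) -> float:
    """Mean best-cluster F1 for the cell types present in the fewest batches.

    Isolated labels are the types observed in the minimum number of batches
    (when every type is in every batch, all types count as isolated). For
    each, the F1 of predicting the label by membership of a single cluster
    is maximised over the Leiden resolution sweep and over clusters.
    """
    celltype = np.asarray(celltype, dtype=object)
    batch = np.asarray(batch, dtype=object)
    n_batches = {
        ct: len(np.unique(batch[celltype == ct])) for ct in np.unique(celltype)
    }
    min_count = min(n_batches.values())
    isolated = sorted([ct for ct, c in n_batches.items() if c == min_count])
    if partitions is None:
        partitions = _leiden_sweep(graph, NMI_RESOLUTIONS, seed)
    scores = []
    for label in isolated:
        truth = (celltype == label).astype(int)
        best = 0.0
        for membership in partitions:
            for cluster in np.unique(membership):
                pred = (membership == cluster).astype(int)
                best = max(best, float(f1_score(truth, pred, zero_division=0)))
        scores.append(best)
    return float(np.mean(scores))


def assess_output(
    output: IntegrationOutput,
    pre_rep: np.ndarray | None,
    batch_key: str = "species",
    celltype_key: str = "cell_type",
    k: int = 20,
    n_dims: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Compute the full metric suite for one integration output.

    Returns a dict over {PCR, bASW, GC, kBET, cASW, NMI, ARI, isoF1, AS};
    metrics that are not applicable to the output kind or label structure
    are reported as NaN. ``pre_rep`` is the unintegrated reference
    embedding required by PCR (same cell order).
    """
    meta = output.cell_meta
    batch = meta[batch_key].to_numpy()
    celltype = meta[celltype_key].to_numpy()
    species = meta["species"].to_numpy()
    graph = output.neighbor_graph(k=k, n_dims=n_dims)

    values: dict[str, float] = {}

    def attempt(name, fn):
        try:
            values[name] = float(fn())
        except MetricNotApplicableError:
            values[name] = float("nan")

    attempt(
        "PCR",
        lambda: principal_component_regression(pre_rep, output.representation(n_dims), batch)
        if pre_rep is not None
        else (_ for _ in ()).throw(MetricNotApplicableError("no unintegrated reference")),
    )
    attempt("bASW", lambda: batch_asw(output.representation(n_dims), batch, celltype, n_dims))
    attempt("GC", lambda: graph_connectivity(graph, celltype))
    attempt(
        "kBET",
        lambda: kbet_acceptance(
            output.representation(n_dims), batch, celltype, k=k, seed=seed
        ),
    )
    attempt("cASW", lambda: celltype_asw(output.representation(n_dims), celltype, n_dims))
    partitions = _leiden_sweep(graph, NMI_RESOLUTIONS, seed)
    attempt("NMI", lambda: optimized_nmi(graph, celltype, seed=seed, partitions=partitions))
    attempt("ARI", lambda: max(ari(celltype, m) for m in partitions))
    attempt(
        "isoF1",
        lambda: isolated_label_f1(celltype, batch, graph, seed=seed, partitions=partitions),
    )
    attempt("AS", lambda: alignment_score(graph, species))
    return values
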