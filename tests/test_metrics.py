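"""Assessment metrics: k-NN graphs, alignment, batch and biology metrics."""

from __future__ import annotations

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from xassess.errors import MetricNotApplicableError, ValidationError
from xassess.metrics import (
    IntegrationOutput,
    NeighborGraph,
    alignment_score,
    ari,
    batch_asw,
    celltype_asw,
    graph_connectivity,
    isolated_label_f1,
    kbet_acceptance,
    knn_graph,
    optimized_nmi,
    principal_component_regression,
    standard_reduce,
)

from conftest import make_adata


def graph_from_edges(n, edges, k):
    adj = sp.lil_matrix((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = True
    return NeighborGraph(adjacency=adj.tocsr(), k=k)


class TestKnnGraph:
    def test_collinear_points(self):
        rep = np.array([[0.0], [1.0], [10.0]])
        graph = knn_graph(rep, k=1)
        assert graph.adjacency[1, 0] and not graph.adjacency[1, 2]

    def test_duplicate_points_tie_break_deterministic(self):
        rep = np.zeros((4, 2))
        g1 = knn_graph(rep, k=2)
        g2 = knn_graph(rep, k=2)
        assert (g1.adjacency != g2.adjacency).nnz == 0
        # equidistant neighbours resolved by ascending index
        assert list(g1.adjacency[3].indices) == [0, 1]

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(11)
        rep = rng.normal(size=(50, 5))
        k = 4
        graph = knn_graph(rep, k=k)
        for i in range(50):
            dists = sorted(
                (math.dist(rep[i], rep[j]), j) for j in range(50) if j != i
            )
            expected = {j for _, j in dists[:k]}
            assert set(graph.adjacency[i].indices) == expected

    def test_no_self_edges_and_degree(self):
        graph = knn_graph(np.random.default_rng(0).normal(size=(30, 3)), k=5)
        assert graph.adjacency.diagonal().sum() == 0
        assert (graph.adjacency.sum(axis=1) == 5).all()

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            knn_graph(np.zeros((3, 2)), k=3)


class TestAlignmentScore:
    def test_all_cross_species_is_one(self):
        graph = graph_from_edges(4, [(0, 2), (1, 3), (2, 0), (3, 1)], k=1)
        assert alignment_score(graph, ["hs", "hs", "mm", "mm"]) == 1.0

    def test_no_cross_species_is_zero(self):
        graph = graph_from_edges(4, [(0, 1), (1, 0), (2, 3), (3, 2)], k=1)
        assert alignment_score(graph, ["hs", "hs", "mm", "mm"]) == 0.0

    def test_half_cross_species_hand_enumerated(self):
        # each cell: 2 neighbours, exactly 1 cross-species; k=2, n_other=2
        edges = [(0, 1), (0, 2), (1, 0), (1, 3), (2, 3), (2, 0), (3, 2), (3, 1)]
        graph = graph_from_edges(4, edges, k=2)
        assert alignment_score(graph, ["hs", "hs", "mm", "mm"]) == 0.5

    def test_denominator_caps_at_other_species_size(self):
        # 3 hs cells, 1 mm cell, k=2: hs cells can have at most 1 cross edge
        edges = [(0, 3), (0, 1), (1, 3), (1, 0), (2, 3), (2, 0), (3, 0), (3, 1)]
        graph = graph_from_edges(4, edges, k=2)
        assert alignment_score(graph, ["hs", "hs", "hs", "mm"]) == 1.0

    def test_single_species_not_applicable(self):
        graph = graph_from_edges(2, [(0, 1), (1, 0)], k=1)
        with pytest.raises(MetricNotApplicableError):
            alignment_score(graph, ["hs", "hs"])

    def test_invariant_to_renaming_and_permutation(self):
        rng = np.random.default_rng(3)
        rep = rng.normal(size=(40, 4))
        species = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        graph = knn_graph(rep, k=5)
        base = alignment_score(graph, species)
        renamed = np.where(species == "a", "zebrafish", "frog")
        assert alignment_score(graph, renamed) == base
        perm = rng.permutation(40)
        graph_p = knn_graph(rep[perm], k=5)
        assert alignment_score(graph_p, species[perm]) == pytest.approx(base, abs=1e-12)


class TestPCR:
    def test_identical_pre_post_is_zero(self):
        rng = np.random.default_rng(0)
        rep = rng.normal(size=(50, 5)) + np.repeat([[0], [4]], 25, axis=0)
        batch = ["a"] * 25 + ["b"] * 25
        assert principal_component_regression(rep, rep, batch) == 0.0

    def test_covariate_independent_post_is_one(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(size=(40, 4)) + np.repeat([[0], [6]], 20, axis=0)
        half = rng.normal(size=(20, 4))
        post = np.vstack([half, half])  # identical per-batch coordinates: R² = 0
        batch = ["a"] * 20 + ["b"] * 20
        assert principal_component_regression(pre, post, batch) == 1.0

    def test_matches_from_scratch_regression_oracle(self):
        rng = np.random.default_rng(7)
        batch = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        pre = rng.normal(size=(100, 6))
        pre[50:] += 3.0
        post = rng.normal(size=(100, 6))
        post[50:, 0] += 0.5

        def oracle_var_expl(rep):
            Xc = rep - rep.mean(axis=0)
            u, s, vt = np.linalg.svd(Xc, full_matrices=False)
            pcs = u * s
            lam = s**2 / (len(rep) - 1)
            total, acc = lam.sum(), 0.0
            for j in range(len(lam)):
                y = pcs[:, j]
                ss_tot = ((y - y.mean()) ** 2).sum()
                ss_res = sum(
                    ((y[batch == g] - y[batch == g].mean()) ** 2).sum()
                    for g in ("a", "b")
                )
                acc += lam[j] * (1 - ss_res / ss_tot)
            return acc / total

        expected = (oracle_var_expl(pre) - oracle_var_expl(post)) / oracle_var_expl(pre)
        expected = min(max(expected, 0.0), 1.0)
        got = principal_component_regression(pre, post, batch)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_zero_pre_variance_not_applicable(self):
        rng = np.random.default_rng(2)
        half = rng.normal(size=(10, 3))
        pre = np.vstack([half, half])
        batch = ["a"] * 10 + ["b"] * 10
        with pytest.raises(MetricNotApplicableError):
            principal_component_regression(pre, pre, batch)


class TestSilhouetteMetrics:
    def test_basw_interleaved_batches_near_one(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(30, 3))
        rep = np.vstack([coords, coords])  # two batches on identical coordinates
        batch = ["a"] * 30 + ["b"] * 30
        celltype = ["t"] * 60
        assert batch_asw(rep, batch, celltype) > 0.95

    def test_basw_separated_batches_near_zero(self):
        rng = np.random.default_rng(5)
        rep = np.vstack(
            [rng.normal(size=(30, 3)), rng.normal(size=(30, 3)) + 50]
        )
        batch = ["a"] * 30 + ["b"] * 30
        assert batch_asw(rep, batch, ["t"] * 60) < 0.05

    def test_basw_single_batch_celltype_excluded(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(20, 3))
        rep = np.vstack([coords, coords, rng.normal(size=(10, 3)) + 30])
        batch = ["a"] * 20 + ["b"] * 20 + ["a"] * 10
        celltype = ["mixed"] * 40 + ["only-a"] * 10
        both = batch_asw(rep, batch, celltype)
        just_mixed = batch_asw(rep[:40], batch[:40], celltype[:40])
        assert both == pytest.approx(just_mixed, abs=1e-12)

    def test_casw_separated_clusters_near_one(self):
        rng = np.random.default_rng(7)
        rep = np.vstack(
            [rng.normal(scale=0.01, size=(20, 3)),
             rng.normal(scale=0.01, size=(20, 3)) + 100]
        )
        celltype = ["x"] * 20 + ["y"] * 20
        assert celltype_asw(rep, celltype) > 0.99

    def test_casw_permuted_labels_near_half(self):
        rng = np.random.default_rng(8)
        rep = np.vstack(
            [rng.normal(size=(100, 3)), rng.normal(size=(100, 3)) + 5]
        )
        labels = rng.permutation(["x"] * 100 + ["y"] * 100)
        assert celltype_asw(rep, labels) == pytest.approx(0.5, abs=0.05)

    def test_casw_formula_lower_bound(self):
        # silhouette of -1 for every cell would map to 0; verify the affine map
        # on the worst observable case: each cell nearer the other cluster
        rep = np.array([[0.0], [10.0], [0.1], [9.9]])
        labels = ["a", "a", "b", "b"]
        value = celltype_asw(rep, labels)
        assert 0 <= value < 0.5


class TestGraphConnectivity:
    def test_fully_connected_types(self):
        edges = [(0, 1), (1, 0), (2, 3), (3, 2)]
        graph = graph_from_edges(4, edges, k=1)
        assert graph_connectivity(graph, ["t1", "t1", "t2", "t2"]) == 1.0

    def test_split_type_hand_built(self):
        # t1: 4 cells in two 2-cell components (0.5); t2: connected pair (1.0)
        edges = [(0, 1), (1, 0), (2, 3), (3, 2), (4, 5), (5, 4)]
        graph = graph_from_edges(6, edges, k=1)
        value = graph_connectivity(graph, ["t1"] * 4 + ["t2"] * 2)
        assert value == (0.5 + 1.0) / 2

    def test_singleton_type_contributes_one(self):
        edges = [(0, 1), (1, 0)]
        graph = graph_from_edges(3, edges, k=1)
        assert graph_connectivity(graph, ["t1", "t1", "lone"]) == 1.0


class TestKbet:
    def test_iid_batches_accepted(self):
        rng = np.random.default_rng(9)
        rep = rng.normal(size=(300, 5))
        batch = rng.choice(["a", "b"], size=300)
        value = kbet_acceptance(rep, batch, ["t"] * 300, k=50, seed=0)
        assert value == pytest.approx(1.0, abs=0.1)

    def test_separated_batches_rejected(self):
        rng = np.random.default_rng(10)
        rep = np.vstack(
            [rng.normal(size=(100, 5)), rng.normal(size=(100, 5)) + 100]
        )
        batch = ["a"] * 100 + ["b"] * 100
        assert kbet_acceptance(rep, batch, ["t"] * 200, k=30, seed=0) < 0.05

    def test_alpha_one_rejects_everything(self):
        rng = np.random.default_rng(11)
        rep = rng.normal(size=(60, 3))
        batch = rng.choice(["a", "b"], size=60)
        assert kbet_acceptance(rep, batch, ["t"] * 60, alpha=1.0, seed=0) == 0.0

    def test_single_batch_not_applicable(self):
        with pytest.raises(MetricNotApplicableError):
            kbet_acceptance(np.zeros((10, 2)), ["a"] * 10, ["t"] * 10)


def brute_force_ari(a, b):
    """Pair-counting ARI, independent of any contingency-table library code."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a, same_b = a[i] == a[j], b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2 * (n11 * n00 - n10 * n01) / denom


def contingency_nmi(a, b):
    """Entropy-based NMI (arithmetic normalisation) from the raw contingency table."""
    a, b = list(a), list(b)
    n = len(a)
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    mi = 0.0
    for ca in cats_a:
        for cb in cats_b:
            nij = sum(1 for x, y in zip(a, b) if x == ca and y == cb)
            if nij:
                ni = a.count(ca)
                nj = b.count(cb)
                mi += (nij / n) * math.log(n * nij / (ni * nj))
    h_a = -sum((a.count(c) / n) * math.log(a.count(c) / n) for c in cats_a)
    h_b = -sum((b.count(c) / n) * math.log(b.count(c) / n) for c in cats_b)
    if h_a + h_b == 0:
        return 1.0
    return mi / ((h_a + h_b) / 2)


class TestClusteringAgreement:
    def test_identical_labelings(self):
        assert ari(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_invariant_under_label_renaming(self):
        a = ["x", "x", "y", "z", "z"]
        b = ["1", "1", "2", "3", "3"]
        assert ari(a, b) == 1.0

    def test_ari_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            assert ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)


class TestOptimizedNmi:
    def test_disconnected_cliques_matching_types(self):
        n_per = 8
        edges = []
        for c in range(3):
            members = range(c * n_per, (c + 1) * n_per)
            edges += [(i, j) for i in members for j in members if i != j]
        graph = graph_from_edges(3 * n_per, edges, k=n_per - 1)
        celltype = np.repeat(["t0", "t1", "t2"], n_per)
        assert optimized_nmi(graph, celltype, seed=0) == pytest.approx(1.0)

    def test_constant_label_is_zero_by_convention(self):
        graph = graph_from_edges(4, [(0, 1), (1, 0), (2, 3), (3, 2)], k=1)
        assert optimized_nmi(graph, ["t"] * 4, seed=0) == 0.0

    def test_nmi_matches_contingency_oracle_at_fixed_clustering(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            got = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert got == pytest.approx(contingency_nmi(a, b), abs=1e-12)


class TestIsolatedLabelF1:
    def graph_and_labels(self):
        # 3 clique clusters of 6; types t0,t1 span batches a+b, t2 only batch a
        n_per = 6
        edges = []
        for c in range(3):
            members = range(c * n_per, (c + 1) * n_per)
            edges += [(i, j) for i in members for j in members if i != j]
        graph = graph_from_edges(3 * n_per, edges, k=n_per - 1)
        celltype = np.repeat(["t0", "t1", "t2"], n_per)
        batch = np.array(["a", "b"] * (3 * n_per // 2))
        batch[celltype == "t2"] = "a"
        return graph, celltype, batch

    def test_isolated_label_in_pure_cluster_scores_one(self):
        graph, celltype, batch = self.graph_and_labels()
        assert isolated_label_f1(celltype, batch, graph, seed=0) == 1.0

    def test_scattered_isolated_label_matches_brute_force(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(14)
        rep = rng.normal(size=(40, 3))
        graph = knn_graph(rep, k=5)
        celltype = np.array(
            ["iso" if i % 4 == 0 else f"t{i % 3}" for i in range(40)], dtype=object
        )
        batch = np.array(["a", "b"] * 20)
        batch[celltype == "iso"] = "a"
        value = isolated_label_f1(celltype, batch, graph, seed=0)
        from xassess.metrics import NMI_RESOLUTIONS, _leiden_sweep

        best = 0.0
        truth = (celltype == "iso").astype(int)
        for membership in _leiden_sweep(graph, NMI_RESOLUTIONS, 0):
            for cluster in np.unique(membership):
                best = max(best, f1_score(truth, (membership == cluster).astype(int)))
        assert value == pytest.approx(best, abs=1e-12)

    def test_mean_over_two_isolated_labels(self):
        # two isolated labels: one pure clique (F1 1.0), one split across cliques
        n_per = 6
        edges = []
        for c in range(3):
            members = range(c * n_per, (c + 1) * n_per)
            edges += [(i, j) for i in members for j in members if i != j]
        graph = graph_from_edges(3 * n_per, edges, k=n_per - 1)
        celltype = np.array(
            ["iso1"] * n_per + ["iso2"] * (n_per // 2) + ["t"] * (n_per // 2) + ["t"] * n_per,
            dtype=object,
        )
        batch = np.array(["a"] * n_per + ["a"] * n_per + ["a", "b"] * (n_per // 2))
        value = isolated_label_f1(celltype, batch, graph, seed=0)
        # iso1 perfectly matches clique 0 -> 1.0; iso2 is half of clique 1:
        # best F1 = 2*3/(3+6) = 2/3
        assert value == pytest.approx((1.0 + 2 / 3) / 2, abs=1e-12)


class TestStandardReduce:
    def test_zero_gene_never_selected(self, dataset):
        adata = dataset.matrices["sp0"]
        padded = ad.AnnData(
            X=np.hstack([np.asarray(adata.X), np.zeros((adata.n_obs, 1))]),
            obs=adata.obs.copy(),
            var=pd.DataFrame(index=list(adata.var_names) + ["flat_gene"]),
        )
        np.testing.assert_allclose(
            standard_reduce(padded), standard_reduce(adata), atol=1e-8
        )

    def test_identical_batches_intersection_equals_per_batch(self, dataset):
        adata = dataset.matrices["sp0"]
        doubled = ad.concat({"b1": adata, "b2": adata}, label="copy", index_unique="-")
        _, both_hvg = standard_reduce(doubled, batch_key="copy", return_hvg=True)

        import warnings

        import scanpy as sc

        work = doubled.copy()
        work.X = work.X.astype(float)
        sc.pp.normalize_total(work, target_sum=1e4)
        sc.pp.log1p(work)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(
                work, min_mean=0.0125, max_mean=3, min_disp=0.5, batch_key="copy"
            )
        # identical batches: every gene is variable in both batches or neither,
        # so the intersection IS the per-batch HVG set
        assert set(work.var["highly_variable_nbatches"]) <= {0, 2}
        expected = set(work.var_names[work.var["highly_variable_intersection"]])
        assert set(both_hvg) == expected

    def test_pca_columns_orthogonal_variance_sorted(self, dataset):
        rep = standard_reduce(dataset.matrices["sp0"])
        cov = rep.T @ rep
        off_diag = cov - np.diag(np.diag(cov))
        assert np.abs(off_diag).max() < 1e-6 * np.abs(np.diag(cov)).max()
        variances = rep.var(axis=0)
        assert (np.diff(variances) <= 1e-9).all()


def test_metric_bounds_on_random_fixtures():
    """All [0,1]-ranged metrics respect their bounds on random inputs."""
    rng = np.random.default_rng(21)
    for trial in range(40):
        n = int(rng.integers(30, 80))
        rep = rng.normal(size=(n, 6)) * rng.uniform(0.5, 5)
        batch = rng.choice(["a", "b", "c"][: int(rng.integers(2, 4))], size=n)
        celltype = rng.choice(["x", "y", "z"][: int(rng.integers(2, 4))], size=n)
        graph = knn_graph(rep, k=5)
        checks = [
            celltype_asw(rep, celltype),
            batch_asw(rep, batch, celltype),
            graph_connectivity(graph, celltype),
            alignment_score(graph, batch),
            kbet_acceptance(rep, batch, celltype, k=10, seed=0),
        ]
        if trial < 5:  # clustering sweeps are costlier; spot-check
            checks.append(optimized_nmi(graph, celltype, seed=0))
            checks.append(isolated_label_f1(celltype, batch, graph, seed=0))
        for value in checks:
            assert 0.0 <= value <= 1.0
        assert ari(celltype, batch) <= 1.0


def test_applicability_contract_for_graph_outputs():
    """Embedding metrics signal not-applicable on graph-only outputs."""
    rng = np.random.default_rng(22)
    rep = rng.normal(size=(30, 4))
    graph = knn_graph(rep, k=4)
    meta = pd.DataFrame(
        {
            "species": ["a", "b"] * 15,
            "batch": ["a", "b"] * 15,
            "cell_type": ["t1", "t2", "t3"] * 10,
        }
    )
    output = IntegrationOutput(
        kind="knn_graph", data=graph.adjacency, strategy="samap", cell_meta=meta
    )
    with pytest.raises(MetricNotApplicableError):
        output.representation()
    # graph metrics still run
    built = output.neighbor_graph()
    assert 0 <= graph_connectivity(built, meta["cell_type"]) <= 1
    assert 0 <= alignment_score(built, meta["species"]) <= 1
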