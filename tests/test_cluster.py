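"""SNN/Leiden clustering, resolution scan, ordering, markers, naming."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from leprmap.cluster import (
    ClusterParams,
    cluster_once,
    find_markers,
    name_clusters,
    optimize_resolution,
    order_clusters,
)
from leprmap.containers import Embedding, NormalizedMatrix
from leprmap.embed import normalize


def _embedding(points):
    points = np.asarray(points, float)
    vf = np.full(points.shape[1], 1.0 / points.shape[1])
    return Embedding(points, vf, points.shape[1])


def _norm(x, genes=None):
    x = np.asarray(x, float)
    return NormalizedMatrix(
        sp.csr_matrix(x),
        np.ones(x.shape[0]),
        [f"c{i}" for i in range(x.shape[0])],
        genes or [f"g{j}" for j in range(x.shape[1])],
    )


class TestClusterOnce:
    def test_two_separated_blobs_give_two_communities(self, rng):
        pts = np.vstack([rng.normal(0, 1, (100, 8)), rng.normal(20, 1, (100, 8))])
        labels = cluster_once(_embedding(pts), ClusterParams(seed=1), resolution=0.2)
        assert len(np.unique(labels)) == 2
        # communities coincide with the blobs
        assert len(np.unique(labels[:100])) == 1 and len(np.unique(labels[100:])) == 1

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(0, 1, (150, 10))
        a = cluster_once(_embedding(pts), ClusterParams(seed=3), resolution=1.0)
        b = cluster_once(_embedding(pts), ClusterParams(seed=3), resolution=1.0)
        np.testing.assert_array_equal(a, b)

    def test_knn_exceeding_cells_raises(self, rng):
        pts = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError):
            cluster_once(_embedding(pts), ClusterParams(knn_k=10), resolution=1.0)


class TestOptimizeResolution:
    def test_grid_is_exactly_point_two_spaced(self, rng):
        pts = np.vstack([rng.normal(i * 10, 1, (60, 5)) for i in range(3)])
        _, log = optimize_resolution(_embedding(pts), ClusterParams(seed=2))
        expected = [round(0.2 * (i + 1), 10) for i in range(len(log))]
        assert log["resolution"].tolist() == expected

    def test_returned_solution_is_scan_argmax(self, rng):
        pts = np.vstack([rng.normal(i * 6, 1, (60, 5)) for i in range(4)])
        sol, log = optimize_resolution(_embedding(pts), ClusterParams(seed=2))
        assert sol.mean_silhouette == pytest.approx(log["mean_silhouette"].max())

    def test_antipodal_blobs_silhouette_above_point_eight(self, rng):
        pts = np.vstack([rng.normal(-20, 1, (80, 4)), rng.normal(20, 1, (80, 4))])
        sol, _ = optimize_resolution(_embedding(pts), ClusterParams(seed=4))
        assert sol.n_clusters == 2
        assert sol.mean_silhouette > 0.8

    def test_labels_partition_cells_at_every_resolution(self, rng):
        pts = np.vstack([rng.normal(i * 8, 1, (50, 5)) for i in range(3)])
        emb = _embedding(pts)
        for res in (0.2, 0.6, 1.4):
            labels = cluster_once(emb, ClusterParams(seed=5), resolution=res)
            assert labels.shape == (150,)
            assert (labels >= 0).all()


class TestOrderClusters:
    def test_collinear_centroids_ordered_by_distance(self, rng):
        pts = np.vstack(
            [
                rng.normal(0, 0.01, (30, 2)),
                rng.normal(1, 0.01, (30, 2)),
                rng.normal(10, 0.01, (30, 2)),
            ]
        )
        labels = np.repeat([0, 1, 2], 30)
        order, lk = order_clusters(_embedding(pts), labels)
        assert abs(order.index(0) - order.index(1)) == 1
        assert order[0] == 2 or order[-1] == 2

    def test_two_clusters_trivial_order(self, rng):
        pts = rng.normal(0, 1, (40, 3))
        labels = np.repeat([0, 1], 20)
        order, _ = order_clusters(_embedding(pts), labels)
        assert sorted(order) == [0, 1]

    def test_single_cluster_identity(self, rng):
        pts = rng.normal(0, 1, (20, 3))
        order, lk = order_clusters(_embedding(pts), np.zeros(20, int))
        assert order == [0] and lk is None


class TestFindMarkers:
    def test_exclusive_gene_is_top_marker(self, rng):
        x = rng.poisson(1.0, (80, 30)).astype(float)
        x[:40, 0] = 5.0
        x[40:, 0] = 0.0
        labels = np.repeat(["A", "B"], 40)
        table = find_markers(_norm(np.log1p(x)), labels)
        top = table[table["cluster"] == "A"].sort_values("log2fc", ascending=False)
        assert top.iloc[0]["gene"] == "g0"
        assert top.iloc[0]["frac_in"] == 1.0 and top.iloc[0]["frac_out"] == 0.0

    def test_agrees_with_per_gene_rank_sum_oracle(self, rng):
        x = np.log1p(rng.poisson(2.0, (60, 25)).astype(float))
        x[:30, :5] += 1.0
        labels = np.repeat(["A", "B"], 30)
        table = find_markers(_norm(x), labels)
        sub = table[table["cluster"] == "A"].set_index("gene")
        # oracle: plain per-gene loop with hand-rolled BH
        in_, out = x[:30], x[30:]
        expm1 = np.expm1(x)
        oracle = {}
        for j in range(25):
            lfc = np.log2(expm1[:30, j].mean() + 1) - np.log2(expm1[30:, j].mean() + 1)
            frac_in = (x[:30, j] > 0).mean()
            if frac_in >= 0.25 and abs(lfc) >= 0.25:
                oracle[f"g{j}"] = mannwhitneyu(
                    in_[:, j], out[:, j], alternative="two-sided"
                ).pvalue
        assert set(oracle) == set(sub.index)
        genes = sorted(oracle)
        p = np.array([oracle[g] for g in genes])
        order = np.argsort(p)
        m = len(p)
        bh = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        fdr = np.empty(m)
        fdr[order] = np.minimum(bh, 1.0)
        for g, p_val, f in zip(genes, p, fdr):
            assert sub.loc[g, "p"] == pytest.approx(p_val)
            assert sub.loc[g, "fdr"] == pytest.approx(f)

    def test_permutation_null_controls_fdr(self, small_atlas):
        """Permuted labels flag at most 5% of the gene panel as markers."""
        counts, truth = small_atlas
        norm = normalize(counts, "library")
        rng = np.random.default_rng(8)
        flagged = 0
        n_perms = 20
        for _ in range(n_perms):
            perm = rng.permutation(truth.population)
            table = find_markers(norm, perm)
            flagged += (table["fdr"] < 0.05).sum()
        assert flagged / (counts.n_genes * n_perms) <= 0.05

    def test_planted_markers_recovered(self, small_atlas):
        counts, truth = small_atlas
        norm = normalize(counts, "library")
        table = find_markers(norm, truth.population)
        for pop, genes in truth.markers.items():
            hits = set(
                table[(table["cluster"] == pop) & (table["fdr"] < 0.05)]["gene"]
            )
            assert set(genes) <= hits


class TestNameClusters:
    def test_unique_marker_names_cluster(self, small_atlas):
        counts, truth = small_atlas
        norm = normalize(counts, "library")
        table = find_markers(norm, truth.population)
        names = name_clusters(table, norm, truth.population)
        for pop in truth.markers:
            assert names[pop] in truth.markers[pop]

    def test_neurochemical_fallback_names(self, rng):
        # two clusters with no unique markers, indicator genes decide
        x = rng.poisson(2.0, (60, 10)).astype(float)
        gaba = np.concatenate([np.full(30, 3.0), np.zeros(30)])
        glu = np.concatenate([np.zeros(30), np.full(30, 3.0)])
        x = np.column_stack([x, gaba, glu])
        genes = [f"g{j}" for j in range(10)] + ["Slc32a1", "Slc17a6"]
        norm = _norm(np.log1p(x), genes)
        labels = np.repeat([0, 1], 30)
        names = name_clusters(pd.DataFrame(
            columns=["cluster", "gene", "log2fc", "frac_in", "frac_out", "p", "fdr"]
        ), norm, labels, tree_order=[0, 1])
        assert names == {0: "GABA", 1: "GLU1"}

    def test_missing_indicators_fall_back_to_unk(self, rng):
        x = np.log1p(rng.poisson(2.0, (40, 8)).astype(float))
        labels = np.repeat([0, 1], 20)
        names = name_clusters(
            pd.DataFrame(columns=["cluster", "gene", "log2fc", "frac_in", "frac_out",
                                  "p", "fdr"]),
            _norm(x), labels, tree_order=[1, 0],
        )
        assert names == {1: "UNK-1", 0: "UNK-2"}
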