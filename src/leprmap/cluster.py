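"""Graph clustering with silhouette-optimized resolution, markers, naming.

Cells are clustered by Leiden modularity optimization on a shared-nearest-
neighbor (SNN) graph built in PC space: kNN sets (cell included) define
Jaccard edge weights, pruned below 1/15.  The resolution parameter is
scanned from 0.2 upward in steps of 0.2 and the partition maximizing the
mean silhouette score (Euclidean, PC coordinates) is returned.  Clusters
are ordered by average-linkage hierarchical clustering of their centroids,
markers are found by one-vs-rest rank-sum tests, and populations are named
by their top unique marker, falling back to neurochemical identity
(GABAergic vs glutamatergic indicator expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import mannwhitneyu
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import ClusterSolution, ConfigurationError, Embedding, NormalizedMatrix

__all__ = [
    "ClusterParams",
    "build_snn_graph",
    "cluster_once",
    "optimize_resolution",
    "order_clusters",
    "find_markers",
    "name_clusters",
]

logger = logging.getLogger(__name__)

SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterParams:
    """Knobs of the SNN graph and the resolution scan."""

    knn_k: int = 20
    resolution_start: float = 0.2
    resolution_step: float = 0.2
    max_resolution: float = 3.0
    patience: int = 2
    silhouette_subsample: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_start <= 0 or self.resolution_step <= 0:
            raise ConfigurationError("resolution start and step must be > 0")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.knn_k < 2:
            raise ConfigurationError("knn_k must be >= 2")


def build_snn_graph(coords: np.ndarray, knn_k: int = 20) -> ig.Graph:
    """SNN graph: Jaccard overlap of kNN sets (self included), pruned."""
    n = coords.shape[0]
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=knn_k).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), knn_k)
    adj = sp.csr_matrix(
        (np.ones(n * knn_k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (adj @ adj.T).tocoo()
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jaccard = shared / (2 * knn_k - shared)
    keep = jaccard >= SNN_PRUNE
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_once(
    embedding: Embedding,
    params: ClusterParams | None = None,
    resolution: float = 1.0,
    graph: ig.Graph | None = None,
) -> np.ndarray:
    """Leiden community detection at one resolution; deterministic given seed."""
    params = params or ClusterParams()
    if graph is None:
        graph = build_snn_graph(embedding.coordinates, params.knn_k)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=params.seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def _mean_silhouette(
    coords: np.ndarray, labels: np.ndarray, subsample: int, seed: int
) -> float:
    if len(np.unique(labels)) < 2:
        return float("-inf")
    n = coords.shape[0]
    if n > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=subsample, replace=False)
        coords, labels = coords[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            return float("-inf")
    return float(silhouette_score(coords, labels, metric="euclidean"))


def optimize_resolution(
    embedding: Embedding, params: ClusterParams | None = None
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Scan resolutions 0.2, 0.4, ... and return the max-silhouette partition.

    The scan stops once the running maximum has not improved for
    ``patience`` consecutive steps or ``max_resolution`` is reached; the
    argmax over all evaluated resolutions is returned regardless.  The
    second return value is the scan log (resolution, n_clusters, mean
    silhouette per row).
    """
    params = params or ClusterParams()
    if embedding.coordinates.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    graph = build_snn_graph(embedding.coordinates, params.knn_k)
    coords = embedding.coordinates

    log_rows = []
    best: ClusterSolution | None = None
    since_best = 0
    res = params.resolution_start
    while res <= params.max_resolution + 1e-9:
        labels = cluster_once(embedding, params, resolution=res, graph=graph)
        sil = _mean_silhouette(
            coords, labels, params.silhouette_subsample, params.seed
        )
        n_clusters = len(np.unique(labels))
        log_rows.append(
            {"resolution": round(res, 10), "n_clusters": n_clusters,
             "mean_silhouette": sil}
        )
        sol = ClusterSolution(labels, round(res, 10), sil, n_clusters)
        if best is None or sil > best.mean_silhouette:
            best = sol
            since_best = 0
        else:
            since_best += 1
        if since_best >= params.patience:
            break
        res += params.resolution_step

    assert best is not None
    if best.n_clusters == 1:
        logger.warning("all resolutions yielded a single cluster")
    return best, pd.DataFrame(log_rows)


def order_clusters(
    embedding: Embedding, labels: np.ndarray
) -> tuple[list, np.ndarray | None]:
    """Hierarchically order clusters by centroid distance in PC space.

    Returns (cluster ids in left-to-right leaf order, average-linkage
    matrix).  A single cluster yields the identity order and no linkage.
    """
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels).tolist())
    if len(ids) < 2:
        return ids, None
    centroids = np.vstack(
        [embedding.coordinates[labels == c].mean(axis=0) for c in ids]
    )
    lk = linkage(centroids, method="average", metric="euclidean")
    order = [ids[i] for i in leaves_list(lk)]
    return order, lk


def find_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    min_frac_in: float = 0.25,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker detection per cluster.

    Genes detected in >= ``min_frac_in`` of the cluster's cells with
    |log2FC| >= ``min_abs_log2fc`` are tested (Wilcoxon rank-sum on
    log-normalized expression); BH correction is applied across tested
    genes within each cluster.  Fold changes compare expm1 means with a
    pseudocount of 1.
    """
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels).tolist())
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    x = np.asarray(norm.values.todense(), dtype=float)
    expm1 = np.expm1(x)
    detected = x > 0

    out = []
    for c in ids:
        members = labels == c
        if members.sum() < 2:
            logger.warning("cluster %s has < 2 cells; skipped", c)
            continue
        m_in = expm1[members].mean(axis=0)
        m_out = expm1[~members].mean(axis=0)
        lfc = np.log2(m_in + 1.0) - np.log2(m_out + 1.0)
        frac_in = detected[members].mean(axis=0)
        frac_out = detected[~members].mean(axis=0)
        testable = (frac_in >= min_frac_in) & (np.abs(lfc) >= min_abs_log2fc)
        if not testable.any():
            continue
        cols = np.flatnonzero(testable)
        stat = mannwhitneyu(
            x[members][:, cols], x[~members][:, cols], axis=0,
            alternative="two-sided",
        )
        fdr = multipletests(stat.pvalue, method="fdr_bh")[1]
        for j, g in enumerate(cols):
            out.append(
                {
                    "cluster": c,
                    "gene": norm.gene_ids[g],
                    "log2fc": lfc[g],
                    "frac_in": frac_in[g],
                    "frac_out": frac_out[g],
                    "p": stat.pvalue[j],
                    "fdr": fdr[j],
                }
            )
    return pd.DataFrame(
        out, columns=["cluster", "gene", "log2fc", "frac_in", "frac_out", "p", "fdr"]
    )


def name_clusters(
    markers: pd.DataFrame,
    norm: NormalizedMatrix,
    labels: np.ndarray,
    tree_order: list | None = None,
    gaba_gene: str = "Slc32a1",
    glu_gene: str = "Slc17a6",
    alpha: float = 0.05,
    max_frac_out: float = 0.1,
) -> dict:
    """Name clusters by their top unique marker, else neurochemical identity.

    A unique marker passes FDR < ``alpha`` with fraction-out <=
    ``max_frac_out`` and positive fold change in exactly one cluster; the
    cluster takes the highest-log2FC such gene (ties lexicographic).
    Remaining clusters are GABA if the GABAergic indicator's mean
    expression exceeds the glutamatergic one, else GLU, numbered in tree
    order (first GABA cluster unnumbered, GLU always numbered).  Missing
    indicator genes yield UNK-n fallback names.
    """
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels).tolist())
    order = tree_order if tree_order is not None else ids

    candidates = markers[
        (markers["fdr"] < alpha)
        & (markers["frac_out"] <= max_frac_out)
        & (markers["log2fc"] > 0)
    ]
    per_gene = candidates.groupby("gene")["cluster"].nunique()
    unique_genes = set(per_gene[per_gene == 1].index)
    unique = candidates[candidates["gene"].isin(unique_genes)]

    names: dict = {}
    for c in ids:
        sub = unique[unique["cluster"] == c]
        if len(sub):
            sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True])
            names[c] = str(sub.iloc[0]["gene"])

    unnamed = [c for c in order if c not in names]
    if unnamed:
        gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
        have_indicators = gaba_gene in gene_index and glu_gene in gene_index
        if not have_indicators:
            logger.warning(
                "indicator genes %s/%s missing; using UNK names", gaba_gene, glu_gene
            )
            for i, c in enumerate(unnamed, start=1):
                names[c] = f"UNK-{i}"
        else:
            x = norm.values
            gaba_col = np.asarray(x[:, gene_index[gaba_gene]].todense()).ravel()
            glu_col = np.asarray(x[:, gene_index[glu_gene]].todense()).ravel()
            n_gaba = n_glu = 0
            for c in unnamed:
                members = labels == c
                if gaba_col[members].mean() > glu_col[members].mean():
                    n_gaba += 1
                    names[c] = "GABA" if n_gaba == 1 else f"GABA{n_gaba}"
                else:
                    n_glu += 1
                    names[c] = f"GLU{n_glu}"
    return names
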