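"""Quality control: retention thresholds and doublet scoring/removal.

Filtering follows the study's rules: genes detected in at least 5 cells are
kept, then cells with at least 600 detected genes among the kept genes.
Doublets are scored by a simulated-doublet k-nearest-neighbor method:
synthetic doublets are formed as sums of random observed cell pairs,
observed and simulated cells are co-embedded in PC space, and each cell's
score reflects how enriched its neighborhood is for simulated doublets.
Cells in clusters with median score > 0.3, and any remaining cell with
score > 0.3, are removed (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ConfigurationError, CountMatrix, EmptyResultError

__all__ = ["QCParams", "filter_matrix", "score_doublets", "apply_doublet_filter"]


@dataclass
class QCParams:
    """Thresholds for gene/cell retention and doublet removal.

    ``doublet_prior`` is the assumed true doublet rate used to convert the
    simulated-neighbor fraction into a [0, 1] score; the default matches
    typical droplet loading rates.
    """

    min_cells_per_gene: int = 5
    min_genes_per_cell: int = 600
    doublet_cut: float = 0.3
    n_sim_doublets: int | None = None  # default: sim_ratio per observed cell
    sim_ratio: float = 2.0
    knn_k: int | None = None  # default: 0.5 * sqrt(n) * (1 + sim_ratio)
    n_pcs: int = 30

    def __post_init__(self) -> None:
        if self.min_cells_per_gene <= 0 or self.min_genes_per_cell <= 0:
            raise ConfigurationError("retention thresholds must be positive")
        if not 0 < self.doublet_cut < 1:
            raise ConfigurationError("doublet_cut must be in (0, 1)")
        if self.sim_ratio <= 0 or self.n_pcs <= 0:
            raise ConfigurationError("sim_ratio and n_pcs must be positive")
        if self.knn_k is not None and self.knn_k <= 0:
            raise ConfigurationError("knn_k must be positive")


def filter_matrix(
    counts: CountMatrix, params: QCParams | None = None
) -> tuple[CountMatrix, dict]:
    """Apply gene then cell retention thresholds.

    Genes detected (count > 0) in >= ``min_cells_per_gene`` cells are kept
    first; then cells with >= ``min_genes_per_cell`` detected genes among
    the kept genes.  The report records the waterfall of counts.
    """
    params = params or QCParams()
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise EmptyResultError("empty input matrix")
    report = {"input_cells": counts.n_cells, "input_genes": counts.n_genes}

    detected = counts.values > 0
    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    gene_mask = cells_per_gene >= params.min_cells_per_gene
    filtered = counts.subset_genes(gene_mask)
    report["genes_after_gene_filter"] = filtered.n_genes

    genes_per_cell = np.asarray((filtered.values > 0).sum(axis=1)).ravel()
    cell_mask = genes_per_cell >= params.min_genes_per_cell
    report["cells_after_cell_filter"] = int(cell_mask.sum())
    if not cell_mask.any():
        raise EmptyResultError(
            "all cells removed by the min_genes_per_cell threshold"
        )
    return filtered.subset_cells(cell_mask), report


def _log_normalize_dense(values: sp.spmatrix) -> np.ndarray:
    totals = np.asarray(values.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0
    factors = totals / totals.mean()
    dense = np.asarray(values.todense(), dtype=float)
    return np.log1p(dense / factors[:, None])


def score_doublets(
    counts: CountMatrix, params: QCParams | None = None, seed: int = 0
) -> np.ndarray:
    """Score each cell's doublet likelihood in [0, 1].

    Simulates synthetic doublets (``sim_ratio`` per observed cell) as sums
    of random observed cell pairs, log-normalizes and standardizes the
    union matrix, embeds it in the top ``n_pcs`` principal components, and
    computes for each observed cell the fraction q of simulated doublets
    among its nearest neighbors (neighborhood size 0.5 * sqrt(n) scaled by
    1 + sim_ratio unless ``knn_k`` overrides it).  The score is q rescaled
    by the expected simulated fraction rho = n_sim / (n_sim + n): the
    excess enrichment (q - rho) / (1 - rho) clipped to [0, 1], so a
    neighborhood no more enriched for simulated doublets than chance
    scores 0 and a purely simulated neighborhood scores 1.
    """
    params = params or QCParams()
    n = counts.n_cells
    n_sim = (
        params.n_sim_doublets
        if params.n_sim_doublets is not None
        else int(round(params.sim_ratio * n))
    )
    if params.knn_k is not None:
        knn_k = params.knn_k
    else:
        knn_k = int(round(0.5 * np.sqrt(n) * (1 + n_sim / n)))
    knn_k = max(knn_k, 3)
    if n < 2 * knn_k:
        raise ValueError(f"need at least {2 * knn_k} cells to score doublets")
    rng = np.random.default_rng(seed)

    pairs = rng.integers(0, n, size=(n_sim, 2))
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n
    sim = counts.values[pairs[:, 0]] + counts.values[pairs[:, 1]]
    union = sp.vstack([counts.values, sim]).tocsr()

    norm = _log_normalize_dense(union)
    norm -= norm.mean(axis=0, keepdims=True)
    sd = norm.std(axis=0)
    norm /= np.where(sd > 0, sd, 1.0)
    n_pcs = min(params.n_pcs, norm.shape[1], norm.shape[0] - 1)
    emb = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed).fit_transform(norm)

    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neighbor_is_sim = (idx[:, 1:] >= n).astype(float)  # drop self
    q = neighbor_is_sim.mean(axis=1)

    rho = n_sim / (n_sim + n)  # expected simulated fraction under no enrichment
    return np.clip((q - rho) / (1.0 - rho), 0.0, 1.0)


def apply_doublet_filter(
    scores: np.ndarray, provisional_clusters: np.ndarray, cut: float = 0.3
) -> np.ndarray:
    """Return the retained-cell mask under the cluster-median + cell rule.

    Removes every cell of any cluster whose median score exceeds ``cut``,
    then any remaining cell whose own score exceeds ``cut``.  Both
    comparisons are strict.
    """
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(provisional_clusters)
    if scores.shape[0] != clusters.shape[0]:
        raise ValueError("scores and cluster labels must be aligned")
    keep = np.ones(scores.shape[0], dtype=bool)
    for c in np.unique(clusters):
        members = clusters == c
        if np.median(scores[members]) > cut:
            keep[members] = False
    keep &= ~(scores > cut)
    return keep
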