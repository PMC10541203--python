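"""Reference label projection and nonneuronal cell removal.

Query cells receive cell-type labels from a labeled reference dataset: the
two scaled matrices are aligned in a joint low-rank space via singular
decomposition of their cross-product (a CCA-style pairing), each query
cell scores every reference type by the mean similarity of that type's
cells among its nearest reference neighbors, and the final label is the
type with the highest summed score over the cell and its 14 nearest
query-side neighbors (a 15-cell vote).  Cells whose assigned type is not
in a neuronal whitelist are then dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from .containers import ConfigurationError, NormalizedMatrix
from .embed import scale_center, select_variable_genes

__all__ = ["TransferParams", "TypeAssignment", "transfer_labels", "drop_nonneuronal"]


@dataclass
class TransferParams:
    """Label-transfer knobs; ``vote_k`` counts the cell itself."""

    vote_k: int = 15
    n_shared_pcs: int = 20
    ref_neighbor_k: int = 20
    n_variable_genes: int = 2000
    neuronal_whitelist: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.vote_k < 1:
            raise ConfigurationError("vote_k must be >= 1")
        if self.n_shared_pcs < 2 or self.ref_neighbor_k < 1:
            raise ConfigurationError("embedding/neighbor sizes must be positive")


@dataclass
class TypeAssignment:
    """Per-cell type call with its vote support and full score matrix."""

    table: pd.DataFrame  # barcode, type, vote_fraction
    scores: pd.DataFrame  # cells x types summed vote scores

    @property
    def types(self) -> np.ndarray:
        return self.table["type"].to_numpy()


def _joint_embedding(
    xq: np.ndarray, xr: np.ndarray, n_dims: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paired low-rank alignment via SVD of the scaled cross-product."""
    k = xq @ xr.T
    n_dims = min(n_dims, min(k.shape) - 1)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(k.shape))
    u, s, vt = svds(k, k=n_dims, v0=v0)
    order = np.argsort(s)[::-1]
    u, vt = u[:, order], vt[order]
    emb_q, emb_r = u, vt.T
    # L2 row normalization puts both datasets on a common shell
    emb_q = emb_q / np.maximum(np.linalg.norm(emb_q, axis=1, keepdims=True), 1e-12)
    emb_r = emb_r / np.maximum(np.linalg.norm(emb_r, axis=1, keepdims=True), 1e-12)
    return emb_q, emb_r


def transfer_labels(
    query: NormalizedMatrix,
    reference: NormalizedMatrix,
    reference_types: np.ndarray,
    params: TransferParams | None = None,
    seed: int = 0,
) -> TypeAssignment:
    """Project reference type labels onto query cells with a 15-cell vote.

    Per-cell per-type score: mean similarity (1 / (1 + distance)) to the
    type's cells among the query cell's ``ref_neighbor_k`` nearest
    reference cells in the joint embedding.  The assigned label maximizes
    the score summed over the cell and its ``vote_k - 1`` nearest
    query-side neighbors; ties break by lexicographic type name.  The vote
    fraction is the share of those cells whose own top type matches the
    winner.
    """
    params = params or TransferParams()
    reference_types = np.asarray(reference_types)
    if len(reference_types) != reference.n_cells:
        raise ValueError("reference labels must align with reference cells")
    type_names = sorted(np.unique(reference_types).tolist())
    if len(type_names) < 2:
        raise ValueError("reference must carry at least 2 types")
    for t in type_names:
        if (reference_types == t).sum() < 3:
            import logging

            logging.getLogger(__name__).warning(
                "reference type %s has < 3 cells", t
            )

    shared = sorted(set(query.gene_ids) & set(reference.gene_ids))
    if not shared:
        raise ValueError("no shared genes between query and reference")
    n_hvg = min(params.n_variable_genes, len(shared))
    ref_shared = _subset_genes(reference, shared)
    hvg = select_variable_genes(ref_shared, n_hvg)
    xq = scale_center(query, hvg)
    xr = scale_center(reference, hvg)
    # the cross-covariance has rank ~ number of types; extra dimensions
    # only add noise to the neighbor structure
    n_dims = min(params.n_shared_pcs, 2 * len(type_names))
    emb_q, emb_r = _joint_embedding(xq, xr, n_dims, seed)

    nn_ref = NearestNeighbors(
        n_neighbors=min(params.ref_neighbor_k, emb_r.shape[0])
    ).fit(emb_r)
    dist, idx = nn_ref.kneighbors(emb_q)
    sim = 1.0 / (1.0 + dist)
    neigh_types = reference_types[idx]
    cell_scores = np.zeros((emb_q.shape[0], len(type_names)))
    for j, t in enumerate(type_names):
        is_t = neigh_types == t
        with np.errstate(invalid="ignore"):
            cell_scores[:, j] = np.where(
                is_t.any(axis=1),
                (sim * is_t).sum(axis=1) / np.maximum(is_t.sum(axis=1), 1),
                0.0,
            )

    k_vote = min(params.vote_k, emb_q.shape[0])
    nn_q = NearestNeighbors(n_neighbors=k_vote).fit(emb_q)
    _, q_idx = nn_q.kneighbors(emb_q)  # includes self as first neighbor
    summed = cell_scores[q_idx].sum(axis=1)
    own_top = cell_scores.argmax(axis=1)

    # argmax with lexicographic tie-break (type_names is sorted)
    winners = summed.argmax(axis=1)
    votes = (own_top[q_idx] == winners[:, None]).mean(axis=1)
    labels = [type_names[w] for w in winners]

    table = pd.DataFrame(
        {"barcode": query.barcodes, "type": labels, "vote_fraction": votes}
    )
    scores = pd.DataFrame(summed, index=query.barcodes, columns=type_names)
    return TypeAssignment(table, scores)


def _subset_genes(norm: NormalizedMatrix, genes: list[str]) -> NormalizedMatrix:
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    cols = [index[g] for g in genes]
    return NormalizedMatrix(
        norm.values[:, cols].tocsr(), norm.size_factors, list(norm.barcodes), list(genes)
    )


def drop_nonneuronal(assignment: TypeAssignment, whitelist: set) -> np.ndarray:
    """Retain cells whose assigned type is in the neuronal whitelist."""
    if not whitelist:
        raise ConfigurationError("neuronal whitelist is empty")
    types = assignment.types
    mask = np.isin(types, sorted(whitelist))
    if not mask.any():
        import logging

        logging.getLogger(__name__).warning(
            "whitelist %s disjoint from assigned types %s",
            sorted(whitelist),
            sorted(set(types.tolist())),
        )
    return mask
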