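"""Cross-species integration and conserved-population matching.

Species datasets are restricted to strictly 1:1 orthologs and renamed into
the reference gene space, embedded together, harmonized with an iterative
soft-cluster centroid correction, and co-clustered.  A combined cluster
absorbing at least 80% of a reference population's cells inherits that
population's name; when two or more populations concentrate in the same
combined cluster it is subclustered (resolution scan within the cluster)
and each contested population goes to the subcluster holding the most of
its cells.  Populations never reaching the threshold are "unmatched".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ConfigurationError, CountMatrix, Embedding
from .cluster import ClusterParams, cluster_once, optimize_resolution

__all__ = [
    "ConserveParams",
    "restrict_to_orthologs",
    "harmonize_batches",
    "match_conserved",
]

logger = logging.getLogger(__name__)


@dataclass
class ConserveParams:
    """Conserved-population matching thresholds."""

    threshold: float = 0.8
    min_cluster_size: int = 10

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1:
            raise ConfigurationError("threshold must be in (0.5, 1]")


def restrict_to_orthologs(counts: CountMatrix, ortholog_map: pd.DataFrame) -> CountMatrix:
    """Keep only mapped genes and rename them to reference ids.

    The map must be strictly 1:1 in both columns.  The cell set is
    unchanged; gene order follows the input matrix.
    """
    for col in ("source_id", "reference_id"):
        if col not in ortholog_map.columns:
            raise ValueError(f"ortholog map missing column {col!r}")
        if ortholog_map[col].duplicated().any():
            raise ValueError(f"ortholog map has duplicate {col}: not 1:1")
    mapping = dict(
        zip(ortholog_map["source_id"], ortholog_map["reference_id"])
    )
    keep = [i for i, g in enumerate(counts.gene_ids) if g in mapping]
    renamed = [mapping[counts.gene_ids[i]] for i in keep]
    return counts.subset_genes(np.asarray(keep, dtype=int), rename=renamed)


def harmonize_batches(
    embedding: Embedding,
    batches: np.ndarray,
    n_clusters: int = 20,
    max_iters: int = 10,
    tol_frac: float = 1e-3,
    seed: int = 0,
) -> Embedding:
    """Remove batch (species) shifts by soft-cluster centroid correction.

    First removes each batch's global mean offset (the one-cluster limit
    of the correction, exact for a pure between-batch shift), then
    alternates a soft k-means assignment in PC space with, per cluster,
    moving each batch's centroid onto the cluster's global centroid (each
    cell is shifted by the responsibility-weighted sum of its batch's
    centroid offsets).  Stops when the largest per-cell displacement falls
    below ``tol_frac`` of the embedding's RMS norm or after ``max_iters``.
    Cell count and dimensionality are unchanged.
    """
    batches = np.asarray(batches)
    z = embedding.coordinates.copy()
    n = z.shape[0]
    if len(batches) != n:
        raise ValueError("batch labels must align with cells")
    batch_names = np.unique(batches)
    if len(batch_names) < 2:
        raise ValueError("need at least 2 batches to harmonize")
    for b in batch_names:
        if (batches == b).sum() < 10:
            logger.warning("batch %s has fewer than 10 cells", b)

    # global per-batch centering: exact for a pure between-batch shift
    global_mean = z.mean(axis=0)
    for b in batch_names:
        members = batches == b
        z[members] += global_mean - z[members].mean(axis=0)

    k = min(n_clusters, max(2, n // 30))
    scale = np.sqrt((z**2).sum(axis=1).mean())
    tol = tol_frac * scale
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(z)
    centers = km.cluster_centers_

    for _ in range(max_iters):
        d2 = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        sigma2 = np.median(d2.min(axis=1)) + 1e-12
        logits = -d2 / (2 * sigma2)
        logits -= logits.max(axis=1, keepdims=True)
        resp = np.exp(logits)
        resp /= resp.sum(axis=1, keepdims=True)

        weights = resp.sum(axis=0)
        centers = (resp.T @ z) / np.maximum(weights[:, None], 1e-12)
        shift = np.zeros_like(z)
        for b in batch_names:
            members = batches == b
            wb = resp[members].sum(axis=0)
            ok = wb > 1e-6
            cb = np.zeros_like(centers)
            cb[ok] = (resp[members].T[ok] @ z[members]) / wb[ok, None]
            offset = np.where(ok[:, None], cb - centers, 0.0)
            shift[members] = resp[members] @ offset
        z = z - shift
        if np.linalg.norm(shift, axis=1).max() < tol:
            break

    return Embedding(
        coordinates=z,
        variance_fraction=embedding.variance_fraction,
        n_pcs=embedding.n_pcs,
        barcodes=list(embedding.barcodes),
    )


def _subcluster(
    embedding: Embedding, member_idx: np.ndarray, params: ClusterParams
) -> np.ndarray:
    """Resolution scan restricted to one cluster's cells; forces a split."""
    sub = Embedding(
        coordinates=embedding.coordinates[member_idx],
        variance_fraction=embedding.variance_fraction,
        n_pcs=embedding.n_pcs,
    )
    sub_params = ClusterParams(
        knn_k=min(params.knn_k, len(member_idx) - 1),
        resolution_start=params.resolution_start,
        resolution_step=params.resolution_step,
        max_resolution=params.max_resolution,
        patience=params.patience,
        seed=params.seed,
    )
    sol, _ = optimize_resolution(sub, sub_params)
    labels = sol.labels
    if len(np.unique(labels)) < 2:
        res = sub_params.resolution_start
        while len(np.unique(labels)) < 2 and res <= sub_params.max_resolution * 2:
            res += sub_params.resolution_step
            labels = cluster_once(sub, sub_params, resolution=res)
    return labels


def match_conserved(
    combined_labels: np.ndarray,
    is_reference: np.ndarray,
    reference_populations: np.ndarray,
    params: ConserveParams | None = None,
    embedding: Embedding | None = None,
    cluster_params: ClusterParams | None = None,
    batches: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Name combined clusters after the reference populations they absorb.

    ``combined_labels`` covers every cell of the combined analysis,
    ``is_reference`` flags the reference dataset's cells and
    ``reference_populations`` gives their population names (aligned with
    the flagged cells).  Returns (conserved map table, population ->
    assigned cluster dict); contested clusters require ``embedding`` for
    subclustering.  Assigned cluster ids are strings, with ``"C.s"`` for
    subcluster s of combined cluster C.
    """
    params = params or ConserveParams()
    combined_labels = np.asarray(combined_labels)
    is_reference = np.asarray(is_reference, dtype=bool)
    reference_populations = np.asarray(reference_populations)
    if not is_reference.any():
        raise ValueError("reference dataset absent from combined data")
    if len(reference_populations) != is_reference.sum():
        raise ValueError("reference population labels misaligned")

    ref_clusters = combined_labels[is_reference]
    pops = sorted(np.unique(reference_populations).tolist())

    # best combined cluster and overlap share per population
    claims: dict[str, tuple] = {}
    for p in pops:
        in_p = reference_populations == p
        counts = pd.Series(ref_clusters[in_p]).value_counts()
        top_cluster = counts.index[0]
        share = counts.iloc[0] / in_p.sum()
        if share >= params.threshold:
            claims[p] = (top_cluster, float(share))

    by_cluster: dict = {}
    for p, (c, share) in claims.items():
        by_cluster.setdefault(c, []).append(p)

    assignment: dict[str, str] = {p: "unmatched" for p in pops}
    overlap: dict[str, float] = {p: claims.get(p, (None, 0.0))[1] for p in pops}
    cluster_rows: dict[str, str] = {}

    for c, contenders in by_cluster.items():
        if len(contenders) == 1:
            p = contenders[0]
            assignment[p] = str(c)
            cluster_rows[str(c)] = p
            continue
        # contested: subcluster and assign each population by plurality
        if embedding is None:
            raise ValueError(
                f"cluster {c} contested by {contenders} but no embedding given"
            )
        member_idx = np.flatnonzero(combined_labels == c)
        sub_labels_local = _subcluster(
            embedding, member_idx, cluster_params or ClusterParams()
        )
        sub_of_cell = dict(zip(member_idx.tolist(), sub_labels_local.tolist()))
        ref_idx = np.flatnonzero(is_reference)
        taken: dict[str, str] = {}
        # larger populations first; exact plurality ties then lexicographic
        pop_sizes = {p: int((reference_populations == p).sum()) for p in contenders}
        for p in sorted(contenders, key=lambda q: (-pop_sizes[q], q)):
            cells_p = ref_idx[reference_populations == p]
            subs = [sub_of_cell[i] for i in cells_p if i in sub_of_cell]
            if not subs:
                continue
            counts = pd.Series(subs).value_counts()
            for s in counts.index:
                sid = f"{c}.{s}"
                if sid not in taken:
                    taken[sid] = p
                    assignment[p] = sid
                    cluster_rows[sid] = p
                    break
            else:
                logger.warning("population %s lost all subcluster ties", p)

    species_comp = {}
    if batches is not None:
        batches = np.asarray(batches)
        for c in np.unique(combined_labels):
            members = combined_labels == c
            comp = pd.Series(batches[members]).value_counts(normalize=True)
            species_comp[str(c)] = {str(k): round(float(v), 4) for k, v in comp.items()}

    rows = []
    for c in sorted(map(str, np.unique(combined_labels).tolist())):
        name = cluster_rows.get(c, c)
        pop = cluster_rows.get(c)
        rows.append(
            {
                "cluster": c,
                "assigned_population": pop if pop is not None else "",
                "overlap_fraction": overlap.get(pop, np.nan) if pop else np.nan,
                "species_composition": species_comp.get(c, {}),
            }
        )
    for sid, p in cluster_rows.items():
        if "." in sid:
            rows.append(
                {
                    "cluster": sid,
                    "assigned_population": p,
                    "overlap_fraction": overlap.get(p, np.nan),
                    "species_composition": {},
                }
            )
    table = pd.DataFrame(rows)
    return table, assignment
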