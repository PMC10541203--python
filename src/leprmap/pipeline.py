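"""End-to-end pipeline orchestration with audited cell-count waterfall.

Stages: read counts -> QC retention filters -> doublet scoring and the
cluster-median removal rule -> normalization, variable genes, scaling,
PC embedding -> optional reference label transfer and nonneuronal
removal -> silhouette-optimized clustering, hierarchical ordering, marker
detection and population naming.  Every intermediate is written as
TSV/JSON under the configured output directory, and every filter logs the
before/after cell counts so the retention waterfall is auditable.

Randomized stages derive their seed from the single run seed plus a fixed
per-stage offset, so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import cluster as cluster_mod
from . import embed as embed_mod
from . import qc as qc_mod
from .config import RunConfig
from .containers import CountMatrix
from .io10x import read_counts_10x

__all__ = ["run_pipeline", "STAGE_SEED_OFFSETS"]

logger = logging.getLogger("leprmap")

STAGE_SEED_OFFSETS = {
    "doublets": 11,
    "normalize": 23,
    "pca": 37,
    "cluster": 53,
    "annotate": 71,
}


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig, counts: CountMatrix | None = None) -> dict:
    """Run the configured stages and write the artifact bundle.

    ``counts`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.counts_dir`` is read.  Returns a dict of in-memory
    artifacts and the paths written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    bundle: dict = {"paths": {}}
    seed = config.seed

    if counts is None:
        counts = _stage("read")(read_counts_10x)(config.counts_dir)
    logger.info("input: %d cells x %d genes", counts.n_cells, counts.n_genes)

    qc_report = {"input_cells": counts.n_cells, "input_genes": counts.n_genes}
    if config.do_qc:
        params = qc_mod.QCParams(
            min_cells_per_gene=config.min_cells,
            min_genes_per_cell=config.min_genes,
            doublet_cut=config.doublet_cut,
        )
        counts, report = _stage("qc")(qc_mod.filter_matrix)(counts, params)
        qc_report.update(report)
        logger.info(
            "gene/cell filter: %d genes, %d cells retained",
            counts.n_genes,
            counts.n_cells,
        )
    else:
        logger.info("stage 'qc' skipped")

    if config.do_doublets:
        counts, doublet_info = _stage("doublets")(_doublet_stage)(
            counts, config, seed + STAGE_SEED_OFFSETS["doublets"]
        )
        qc_report.update(doublet_info)
        logger.info("doublet filter: %d cells retained", counts.n_cells)
    else:
        logger.info("stage 'doublets' skipped")

    norm = _stage("normalize")(embed_mod.normalize)(
        counts, config.normalization, seed=seed + STAGE_SEED_OFFSETS["normalize"]
    )
    hvg = _stage("variable_genes")(embed_mod.select_variable_genes)(
        norm, min(config.n_hvg, norm.n_genes)
    )
    scaled = _stage("scale")(embed_mod.scale_center)(norm, hvg, config.scale_clip)
    embedding = _stage("pca")(embed_mod.pca_elbow)(
        scaled,
        pc_min=min(config.pc_min, counts.n_cells - 2),
        pc_max=min(config.pc_max, counts.n_cells - 1),
        seed=seed + STAGE_SEED_OFFSETS["pca"],
        barcodes=list(counts.barcodes),
    )
    logger.info("embedding: %d PCs retained", embedding.n_pcs)

    if config.do_annotate and config.reference_dir:
        counts, norm, embedding, assignment = _stage("annotate")(_annotate_stage)(
            counts, norm, config, seed + STAGE_SEED_OFFSETS["annotate"]
        )
        bundle["assignment"] = assignment
        qc_report["cells_after_neuronal_filter"] = counts.n_cells
        logger.info("nonneuronal filter: %d cells retained", counts.n_cells)
        assignment.table.to_csv(out_dir / "assignment.tsv", sep="\t", index=False)
        bundle["paths"]["assignment"] = out_dir / "assignment.tsv"
    elif config.do_annotate:
        logger.info("stage 'annotate' skipped (no reference_dir)")

    if config.do_cluster:
        params = cluster_mod.ClusterParams(
            knn_k=min(config.knn_k, counts.n_cells - 1),
            resolution_start=config.resolution_start,
            resolution_step=config.resolution_step,
            max_resolution=config.max_resolution,
            seed=seed + STAGE_SEED_OFFSETS["cluster"],
        )
        solution, scan_log = _stage("cluster")(cluster_mod.optimize_resolution)(
            embedding, params
        )
        logger.info(
            "clustering: %d clusters at resolution %.1f (mean silhouette %.3f)",
            solution.n_clusters,
            solution.resolution,
            solution.mean_silhouette,
        )
        tree_order, _ = cluster_mod.order_clusters(embedding, solution.labels)
        markers = (
            _stage("markers")(cluster_mod.find_markers)(norm, solution.labels)
            if solution.n_clusters >= 2
            else pd.DataFrame()
        )
        names = (
            cluster_mod.name_clusters(markers, norm, solution.labels, tree_order)
            if len(markers)
            else {c: f"UNK-{i+1}" for i, c in enumerate(tree_order)}
        )
        cluster_table = pd.DataFrame(
            {
                "barcode": counts.barcodes,
                "cluster": solution.labels,
                "cluster_name": [names[c] for c in solution.labels],
                "resolution": solution.resolution,
            }
        )
        cluster_table.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        markers.to_csv(out_dir / "markers.tsv", sep="\t", index=False)
        scan_log.to_csv(out_dir / "resolution_scan.tsv", sep="\t", index=False)
        bundle.update(
            solution=solution,
            scan_log=scan_log,
            markers=markers,
            names=names,
            tree_order=tree_order,
            cluster_table=cluster_table,
        )
        bundle["paths"].update(
            clusters=out_dir / "clusters.tsv",
            markers=out_dir / "markers.tsv",
            scan_log=out_dir / "resolution_scan.tsv",
        )
    else:
        logger.info("stage 'cluster' skipped")

    emb_table = pd.DataFrame(
        embedding.coordinates,
        columns=[f"PC{i+1}" for i in range(embedding.n_pcs)],
    )
    emb_table.insert(0, "barcode", counts.barcodes)
    emb_table.to_csv(out_dir / "embedding.tsv", sep="\t", index=False)
    with open(out_dir / "embedding.json", "w") as fh:
        json.dump(
            {
                "n_pcs": embedding.n_pcs,
                "variance_fraction": embedding.variance_fraction.tolist(),
            },
            fh,
            indent=2,
        )
    with open(out_dir / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2, sort_keys=True)
    pd.Series(qc_report).rename("count").to_csv(out_dir / "qc_report.tsv", sep="\t")

    bundle.update(counts=counts, norm=norm, embedding=embedding, qc_report=qc_report)
    bundle["paths"].update(
        embedding=out_dir / "embedding.tsv", qc_report=out_dir / "qc_report.json"
    )
    return bundle


def _doublet_stage(counts: CountMatrix, config: RunConfig, seed: int):
    params = qc_mod.QCParams(doublet_cut=config.doublet_cut)
    scores = qc_mod.score_doublets(counts, params, seed=seed)
    # quick fixed-resolution pass provides the clusters for the median rule
    norm = embed_mod.normalize(counts, "library")
    hvg = embed_mod.select_variable_genes(norm, min(config.n_hvg, norm.n_genes))
    scaled = embed_mod.scale_center(norm, hvg)
    embedding = embed_mod.pca_elbow(
        scaled,
        pc_min=min(config.pc_min, counts.n_cells - 2),
        pc_max=min(config.pc_max, counts.n_cells - 1),
        seed=seed,
    )
    provisional = cluster_mod.cluster_once(
        embedding,
        cluster_mod.ClusterParams(knn_k=min(config.knn_k, counts.n_cells - 1), seed=seed),
        resolution=1.0,
    )
    keep = qc_mod.apply_doublet_filter(scores, provisional, config.doublet_cut)
    info = {
        "cells_before_doublet_filter": counts.n_cells,
        "cells_after_doublet_filter": int(keep.sum()),
    }
    return counts.subset_cells(keep), info


def _annotate_stage(counts, norm, config: RunConfig, seed: int):
    reference = read_counts_10x(config.reference_dir)
    labels_df = pd.read_csv(config.reference_labels, sep="\t")
    ref_types = (
        labels_df.set_index(labels_df.columns[0])
        .loc[reference.barcodes, labels_df.columns[1]]
        .to_numpy()
    )
    ref_norm = embed_mod.normalize(reference, "library")
    params = annotate_mod.TransferParams(
        vote_k=config.vote_k,
        neuronal_whitelist=set(config.neuronal_whitelist),
    )
    assignment = annotate_mod.transfer_labels(norm, ref_norm, ref_types, params, seed=seed)
    mask = annotate_mod.drop_nonneuronal(assignment, set(config.neuronal_whitelist))
    counts = counts.subset_cells(mask)
    norm = embed_mod.normalize(counts, config.normalization, seed=seed)
    hvg = embed_mod.select_variable_genes(norm, min(config.n_hvg, norm.n_genes))
    scaled = embed_mod.scale_center(norm, hvg, config.scale_clip)
    embedding = embed_mod.pca_elbow(
        scaled,
        pc_min=min(config.pc_min, counts.n_cells - 2),
        pc_max=min(config.pc_max, counts.n_cells - 1),
        seed=seed,
        barcodes=list(counts.barcodes),
    )
    return counts, norm, embedding, assignment
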