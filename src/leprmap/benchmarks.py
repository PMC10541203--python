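"""Desk-scale benchmark experiments with known ground truth.

Each function generates its own synthetic inputs from a seed, runs the
relevant pipeline stages, and returns the evaluation metrics.  These are
the experiments the analysis drivers and the acceptance checks run; the
problem sizes mirror the standard study conditions of the synthetic
generator (6 populations x 300 cells, 2,000 genes, 40 markers per
population at log2 fold change 3; 4 bead/sup pairs at dispersion 0.1 for
TRAP enrichment, 12 pairs for the leptin-response design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import annotate as annotate_mod
from . import cluster as cluster_mod
from . import conserve as conserve_mod
from . import embed as embed_mod
from . import qc as qc_mod
from . import trap as trap_mod
from .containers import CountMatrix, Embedding
from .synthetic import (
    AtlasSpec,
    SpeciesPanelSpec,
    TrapSpec,
    inject_doublets,
    make_atlas,
    make_species_panel,
    make_trap_experiment,
)

__all__ = [
    "cluster_recovery_benchmark",
    "doublet_benchmark",
    "label_transfer_benchmark",
    "conserved_matching_benchmark",
    "de_calibration_benchmark",
    "signature_score_benchmark",
]


def _standard_atlas_spec(seed: int) -> AtlasSpec:
    return AtlasSpec(
        n_populations=6,
        cells_per_population=300,
        n_genes=2000,
        markers_per_population=40,
        marker_log2fc=3.0,
        seed=seed,
    )


def _embed(counts: CountMatrix, seed: int, n_hvg: int = 2000) -> tuple:
    norm = embed_mod.normalize(counts, "pooled", seed=seed)
    hvg = embed_mod.select_variable_genes(norm, min(n_hvg, norm.n_genes))
    scaled = embed_mod.scale_center(norm, hvg)
    embedding = embed_mod.pca_elbow(scaled, seed=seed, barcodes=list(counts.barcodes))
    return norm, embedding


def cluster_recovery_benchmark(seed: int) -> dict:
    """Full QC -> doublet -> embed -> resolution scan on the standard atlas.

    Returns the adjusted Rand index of the selected partition against the
    planted populations, plus the resolution-scan log so the argmax and
    grid contracts can be checked.
    """
    counts, truth = make_atlas(_standard_atlas_spec(seed))
    truth_by_barcode = dict(zip(counts.barcodes, truth.population))

    filtered, _ = qc_mod.filter_matrix(counts, qc_mod.QCParams())
    scores = qc_mod.score_doublets(filtered, seed=seed + 1)
    norm0, emb0 = _embed(filtered, seed + 2)
    provisional = cluster_mod.cluster_once(
        emb0, cluster_mod.ClusterParams(seed=seed + 2), resolution=1.0
    )
    keep = qc_mod.apply_doublet_filter(scores, provisional)
    retained = filtered.subset_cells(keep)

    _, embedding = _embed(retained, seed + 3)
    solution, scan_log = cluster_mod.optimize_resolution(
        embedding, cluster_mod.ClusterParams(seed=seed + 4)
    )
    truth_labels = [truth_by_barcode[b] for b in retained.barcodes]
    ari = adjusted_rand_score(truth_labels, solution.labels)
    grid_ok = all(
        abs(r - 0.2 * (i + 1)) < 1e-9
        for i, r in enumerate(scan_log["resolution"])
    )
    return {
        "ari": float(ari),
        "n_cells": retained.n_cells,
        "n_clusters": solution.n_clusters,
        "mean_silhouette": solution.mean_silhouette,
        "scan_log": scan_log,
        "grid_ok": bool(grid_ok),
    }


def doublet_benchmark(seed: int, rate: float = 0.10) -> dict:
    """Score and remove injected doublets on the standard atlas."""
    counts, truth = make_atlas(_standard_atlas_spec(seed))
    mixed, mixed_truth = inject_doublets(counts, truth, rate, seed=seed + 1)
    scores = qc_mod.score_doublets(mixed, seed=seed + 2)
    auroc = roc_auc_score(mixed_truth.is_doublet, scores)

    _, embedding = _embed(mixed, seed + 3)
    provisional = cluster_mod.cluster_once(
        embedding, cluster_mod.ClusterParams(seed=seed + 3), resolution=1.0
    )
    keep = qc_mod.apply_doublet_filter(scores, provisional)
    is_doublet = mixed_truth.is_doublet
    return {
        "auroc": float(auroc),
        "doublet_removal_sensitivity": float((~keep[is_doublet]).mean()),
        "singlet_loss": float((~keep[~is_doublet]).mean()),
        "n_cells": mixed.n_cells,
    }


def label_transfer_benchmark(seed: int) -> dict:
    """Held-out label transfer and contaminant removal on a split atlas."""
    spec = AtlasSpec(
        n_populations=6,
        cells_per_population=250,
        n_genes=1500,
        markers_per_population=40,
        marker_log2fc=3.0,
        frac_contaminant_cells=0.10,
        seed=seed,
    )
    counts, truth = make_atlas(spec)
    rng = np.random.default_rng(seed + 1)
    idx = rng.permutation(counts.n_cells)
    half = counts.n_cells // 2
    ref_idx, query_idx = idx[:half], idx[half:]

    def types(i):
        return np.where(truth.is_contaminant[i], "NonNeuronal", truth.population[i])

    ref = embed_mod.normalize(counts.subset_cells(ref_idx), "library")
    query = embed_mod.normalize(counts.subset_cells(query_idx), "library")
    assignment = annotate_mod.transfer_labels(
        query, ref, types(ref_idx), seed=seed + 2
    )
    accuracy = float((assignment.types == types(query_idx)).mean())

    whitelist = {f"P{i + 1}" for i in range(spec.n_populations)}
    mask = annotate_mod.drop_nonneuronal(assignment, whitelist)
    contaminant = truth.is_contaminant[query_idx]
    return {
        "accuracy": accuracy,
        "contaminant_removal_sensitivity": float((~mask[contaminant]).mean()),
        "neuron_loss": float((~mask[~contaminant]).mean()),
        "n_query_cells": len(query_idx),
    }


def integrate_species_panel(panel, seed: int) -> dict:
    """Combined ortholog-space analysis of a species panel.

    Restricts each species to its 1:1 orthologs, intersects the reference
    gene space, co-embeds, harmonizes species, co-clusters, and matches
    combined clusters to the reference (species_0) populations.
    """
    restricted = [
        conserve_mod.restrict_to_orthologs(c, m) for c, _, m in panel
    ]
    shared = sorted(set.intersection(*(set(r.gene_ids) for r in restricted)))
    aligned = []
    for r in restricted:
        index = {g: i for i, g in enumerate(r.gene_ids)}
        aligned.append(
            r.subset_genes(np.array([index[g] for g in shared]), rename=list(shared))
        )
    values = sp.vstack([m.values for m in aligned]).tocsr()
    barcodes = [b for m in aligned for b in m.barcodes]
    combined = CountMatrix(values, barcodes, list(shared))
    batches = np.concatenate(
        [np.repeat(m.species, m.n_cells) for m in aligned]
    )

    norm = embed_mod.normalize(combined, "library")
    hvg = embed_mod.select_variable_genes(norm, min(2000, norm.n_genes))
    scaled = embed_mod.scale_center(norm, hvg)
    embedding = embed_mod.pca_elbow(scaled, seed=seed, barcodes=barcodes)
    harmonized = conserve_mod.harmonize_batches(embedding, batches, seed=seed + 1)
    solution, _ = cluster_mod.optimize_resolution(
        harmonized, cluster_mod.ClusterParams(seed=seed + 2)
    )
    is_ref = batches == panel[0][0].species
    ref_pops = panel[0][1].population
    table, assignment = conserve_mod.match_conserved(
        solution.labels,
        is_ref,
        ref_pops,
        embedding=harmonized,
        cluster_params=cluster_mod.ClusterParams(seed=seed + 3),
        batches=batches,
    )
    return {
        "assignment": assignment,
        "table": table,
        "solution": solution,
        "batches": batches,
    }


def conserved_matching_benchmark(seed: int) -> dict:
    """Two-species panel, 80% ortholog coverage, moderate species shift."""
    base = AtlasSpec(
        n_populations=6,
        cells_per_population=200,
        n_genes=1500,
        markers_per_population=40,
        marker_log2fc=3.0,
        seed=seed,
    )
    panel = make_species_panel(
        SpeciesPanelSpec(
            base=base, n_species=2, ortholog_coverage=0.8, species_shift_sd=0.2
        )
    )
    result = integrate_species_panel(panel, seed + 10)
    assignment = result["assignment"]
    matched = sum(v != "unmatched" for v in assignment.values())
    return {
        "recovery": matched / len(assignment),
        "assignment": assignment,
        "n_cells": int(len(result["batches"])),
    }


def contested_cluster_fixture(seed: int) -> dict:
    """Planted contested-cluster case: two populations merged into one
    combined cluster whose subclusters separate them cleanly."""
    rng = np.random.default_rng(seed)
    n = 120
    blobs = [rng.normal(loc, 0.5, (n, 4)) for loc in (0.0, 8.0, 30.0)]
    emb = Embedding(np.vstack(blobs), np.full(4, 0.1), 4)
    combined = np.array([0] * (2 * n) + [1] * n)
    is_ref = np.tile([True, False], 3 * n // 2)
    pops = np.array(["A"] * (n // 2) + ["B"] * (n // 2) + ["C"] * (n // 2))
    _, assignment = conserve_mod.match_conserved(
        combined,
        is_ref,
        pops,
        embedding=emb,
        cluster_params=cluster_mod.ClusterParams(seed=seed),
    )
    resolved = (
        assignment["A"].startswith("0.")
        and assignment["B"].startswith("0.")
        and assignment["A"] != assignment["B"]
        and assignment["C"] == "1"
    )
    return {"resolved": bool(resolved), "assignment": assignment}


def de_calibration_benchmark(seed: int) -> dict:
    """Global-null false-discovery control and planted-enrichment power."""
    null_counts, null_meta, _ = make_trap_experiment(
        TrapSpec(
            n_pairs=4, n_genes=2000, enrichment_log2fc=0.0,
            leptin_log2fc=0.0, dispersion=0.1, seed=seed,
        )
    )
    null_de = trap_mod.fit_nb_de(null_counts, null_meta, "pair+fraction")
    null_fraction = float((null_de["fdr"] < 0.05).fillna(False).mean())

    counts, meta, truth = make_trap_experiment(
        TrapSpec(
            n_pairs=4, n_genes=2000, enrichment_log2fc=2.0, dispersion=0.1,
            seed=seed + 1,
        )
    )
    de = trap_mod.fit_nb_de(counts, meta, "pair+fraction")
    enriched = truth.set_index("gene")["enriched"]
    hits = (de["fdr"] < 0.05).fillna(False)
    power = float(hits[enriched].mean())
    mc_se = float(np.sqrt(0.05 * 0.95 / 2000))
    return {
        "null_fdr_fraction": null_fraction,
        "power": power,
        "mc_se": mc_se,
        "n_genes": 2000,
    }


def signature_score_benchmark(seed: int) -> dict:
    """Graded-responsiveness fixture: population ranking and invariances."""
    rng = np.random.default_rng(seed)
    grades = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
    n_sig, per_pop = 20, 80
    signs = rng.choice([-1, 1], n_sig)
    pops = np.repeat([f"pop{i}" for i in range(5)], per_pop)
    expr = np.repeat(grades, per_pop)[:, None] * signs[None, :]
    expr = expr + rng.normal(0, 0.4, expr.shape)
    extra = rng.normal(0, 1, (len(pops), 30))
    mat = np.column_stack([expr, extra])
    mat = (mat - mat.mean(0)) / mat.std(0)
    genes = [f"S{i:02d}" for i in range(n_sig)] + [f"X{i:02d}" for i in range(30)]

    sig = trap_mod.Signature(genes=genes[:n_sig], signs=signs)
    res = trap_mod.score_signature(mat, genes, sig, pops)
    by_pop = res.per_population.set_index("population")["score"]
    scores = by_pop.loc[[f"pop{i}" for i in range(5)]].to_numpy()
    ranking_exact = bool((np.argsort(scores) == np.argsort(grades)).all())
    # exact rank agreement means Spearman rho of exactly 1
    rho = 1.0 if ranking_exact else float(spearmanr(scores, grades).statistic)

    perm = rng.permutation(n_sig)
    sig_perm = trap_mod.Signature(
        genes=[genes[i] for i in perm], signs=signs[perm]
    )
    res_perm = trap_mod.score_signature(mat, genes, sig_perm, pops)
    order_dev = float(np.max(np.abs(res.per_cell - res_perm.per_cell)))
    return {
        "spearman": rho,
        "ranking_exact": ranking_exact,
        "gene_order_max_dev": order_dev,
        "population_scores": dict(zip(by_pop.index, by_pop.to_numpy())),
        "n_cells": len(pops),
    }
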