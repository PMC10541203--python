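"""Synthetic single-nucleus and TRAP-seq data with known ground truth.

The generators emulate the structure of the real inputs the pipeline was
designed for: multi-population negative-binomial count matrices with planted
marker genes, nonneuronal contaminant cells, doublets formed as sums of two
nuclei, multi-species replicas of shared populations linked by partial 1:1
ortholog maps, and paired bead/supernatant TRAP-seq counts with planted
enrichment and leptin-response effects.

Counts follow a negative binomial parameterized by mean ``m`` and dispersion
``phi`` (variance ``m + phi * m**2``), drawn as a gamma-Poisson mixture.
Per-cell library-size factors are log-normal with mean 1 and the requested
coefficient of variation.  Every generator draws from a single
``numpy.random.default_rng`` stream seeded by its spec, so outputs are
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ConfigurationError, CountMatrix

__all__ = [
    "AtlasSpec",
    "TruthLabels",
    "SpeciesPanelSpec",
    "TrapSpec",
    "make_atlas",
    "inject_doublets",
    "make_species_panel",
    "make_trap_experiment",
]


@dataclass
class AtlasSpec:
    """Parameters of a multi-population synthetic nucleus atlas."""

    n_populations: int = 6
    cells_per_population: int = 300
    n_genes: int = 2000
    markers_per_population: int = 40
    marker_log2fc: float = 3.0
    baseline_mean: float = 1.0
    dispersion: float = 0.2
    libsize_cv: float = 0.3
    frac_contaminant_cells: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.cells_per_population < 1:
            raise ConfigurationError("population counts must be positive")
        if self.n_genes < 1 or self.markers_per_population < 0:
            raise ConfigurationError("gene counts must be positive")
        if self.markers_per_population * self.n_populations > self.n_genes:
            raise ConfigurationError(
                "markers_per_population * n_populations exceeds n_genes"
            )
        if self.marker_log2fc < 0:
            raise ConfigurationError("marker_log2fc must be >= 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be > 0")
        if self.libsize_cv < 0:
            raise ConfigurationError("libsize_cv must be >= 0")
        if not 0 <= self.frac_contaminant_cells < 1:
            raise ConfigurationError("frac_contaminant_cells must be in [0, 1)")


@dataclass
class TruthLabels:
    """Ground-truth annotation for generated cells.

    ``doublet_parents`` holds, for each cell, the row indices of the two
    singlets summed to form it (-1, -1 for singlets).
    """

    population: np.ndarray
    is_doublet: np.ndarray
    is_contaminant: np.ndarray
    markers: dict[str, list[str]] = field(default_factory=dict)
    doublet_parents: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.population)
        if len(self.is_doublet) != n or len(self.is_contaminant) != n:
            raise ValueError("truth label arrays must share one length")
        if self.doublet_parents is None:
            self.doublet_parents = np.full((n, 2), -1, dtype=int)
        marker_union: set[str] = set()
        for genes in self.markers.values():
            if marker_union & set(genes):
                raise ValueError("marker lists must be disjoint across populations")
            marker_union |= set(genes)

    def to_frame(self, barcodes: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": barcodes,
                "population": self.population,
                "is_doublet": self.is_doublet.astype(int),
                "is_contaminant": self.is_contaminant.astype(int),
            }
        )


@dataclass
class SpeciesPanelSpec:
    """A shared atlas replicated across species with ortholog bookkeeping."""

    base: AtlasSpec = field(default_factory=AtlasSpec)
    n_species: int = 2
    ortholog_coverage: float = 0.8
    species_shift_sd: float = 0.1
    gene_rename_scheme: str = "prefix"

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        if not 0 < self.ortholog_coverage <= 1:
            raise ConfigurationError("ortholog_coverage must be in (0, 1]")
        if self.species_shift_sd < 0:
            raise ConfigurationError("species_shift_sd must be >= 0")


@dataclass
class TrapSpec:
    """Paired bead/sup TRAP-seq experiment with planted effects."""

    n_pairs: int = 4
    n_genes: int = 2000
    frac_enriched: float = 0.1
    enrichment_log2fc: float = 2.0
    frac_leptin_responsive: float = 0.1
    leptin_log2fc: float = 1.5
    genotypes: tuple[str, str] = ("WT", "ob/ob")
    dispersion: float = 0.1
    baseline_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError(
                "n_pairs must be >= 2 (paired model unidentifiable otherwise)"
            )
        for frac in (self.frac_enriched, self.frac_leptin_responsive):
            if not 0 < frac < 1:
                raise ConfigurationError("effect fractions must be in (0, 1)")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigurationError("dispersion and baseline_mean must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + dispersion * mean**2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) * dispersion)
    return rng.poisson(lam)


def _libsize_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def _population_means(spec: AtlasSpec, rng: np.random.Generator):
    """Build per-population mean matrices and the planted marker map."""
    gene_ids = _gene_ids(spec.n_genes)
    # moderate gene-level heterogeneity around the requested baseline
    sigma = 0.5
    base = spec.baseline_mean * rng.lognormal(-(sigma**2) / 2, sigma, size=spec.n_genes)
    fold = 2.0**spec.marker_log2fc
    # marker genes are near-silent outside their population (as real
    # population markers are) and elevated by the fold change inside
    off_scale = 0.1
    pop_names = [f"P{i + 1}" for i in range(spec.n_populations)]
    markers: dict[str, list[str]] = {}
    n_marked = spec.n_populations * spec.markers_per_population
    marker_base = base.copy()
    # planted markers sit at the nominal baseline (no lognormal tail) so
    # every marker is a reliably expressed gene, as curated markers are
    marker_base[:n_marked] = off_scale * spec.baseline_mean
    has_pseudo = spec.n_genes - n_marked >= spec.markers_per_population > 0
    if has_pseudo:
        marker_base[-spec.markers_per_population :] = off_scale * spec.baseline_mean
    means = {}
    for i, name in enumerate(pop_names):
        lo = i * spec.markers_per_population
        hi = lo + spec.markers_per_population
        mu = marker_base.copy()
        mu[lo:hi] *= fold
        markers[name] = gene_ids[lo:hi]
        means[name] = mu
    # contaminant profile: independent (permuted) means for non-marker
    # genes plus distinctive pseudo-genes from the tail of the panel
    contam = marker_base[rng.permutation(spec.n_genes)]
    contam[:n_marked] = marker_base[:n_marked]
    if has_pseudo:
        contam[-spec.markers_per_population :] = (
            marker_base[-spec.markers_per_population :] * fold
        )
        markers["NonNeuronal"] = gene_ids[-spec.markers_per_population :]
    return gene_ids, pop_names, means, contam, markers


def make_atlas(spec: AtlasSpec) -> tuple[CountMatrix, TruthLabels]:
    """Generate a multi-population NB count matrix with planted markers.

    Cells are ordered population by population with contaminant cells
    appended; ``frac_contaminant_cells`` is the contaminant share of the
    final cell total.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids, pop_names, means, contam_mu, markers = _population_means(spec, rng)

    n_singlets = spec.n_populations * spec.cells_per_population
    frac = spec.frac_contaminant_cells
    n_contam = int(round(n_singlets * frac / (1.0 - frac))) if frac > 0 else 0

    pops = np.repeat(pop_names, spec.cells_per_population)
    pops = np.concatenate([pops, np.repeat("NonNeuronal", n_contam)])
    n_cells = len(pops)
    factors = _libsize_factors(rng, n_cells, spec.libsize_cv)

    rows = []
    for i, pop in enumerate(pops):
        mu = contam_mu if pop == "NonNeuronal" else means[pop]
        rows.append(_nb_draw(rng, factors[i] * mu, spec.dispersion))
    values = sp.csr_matrix(np.vstack(rows))

    barcodes = [f"cell-{i:05d}" for i in range(n_cells)]
    truth = TruthLabels(
        population=pops,
        is_doublet=np.zeros(n_cells, dtype=bool),
        is_contaminant=(pops == "NonNeuronal"),
        markers={k: v for k, v in markers.items() if k != "NonNeuronal"},
    )
    return CountMatrix(values, barcodes, gene_ids), truth


def inject_doublets(
    counts: CountMatrix, truth: TruthLabels, rate: float, seed: int = 0
) -> tuple[CountMatrix, TruthLabels]:
    """Append round(rate * n_cells) doublets, each the sum of two singlets.

    Parents are sampled uniformly without replacement per doublet from the
    existing cells; the returned truth flags the new rows and records the
    parent row indices.
    """
    if not 0 <= rate <= 0.5:
        raise ConfigurationError("doublet rate must be in [0, 0.5]")
    n = counts.n_cells
    n_doublets = int(round(rate * n))
    if n_doublets == 0:
        return counts, truth
    rng = np.random.default_rng(seed)
    parents = np.array([rng.choice(n, size=2, replace=False) for _ in range(n_doublets)])
    dense = counts.values
    doublet_rows = dense[parents[:, 0]] + dense[parents[:, 1]]
    values = sp.vstack([counts.values, sp.csr_matrix(doublet_rows)]).tocsr()
    barcodes = counts.barcodes + [f"doublet-{i:05d}" for i in range(n_doublets)]

    population = np.concatenate([truth.population, np.repeat("Doublet", n_doublets)])
    is_doublet = np.concatenate(
        [truth.is_doublet, np.ones(n_doublets, dtype=bool)]
    )
    is_contaminant = np.concatenate(
        [truth.is_contaminant, np.zeros(n_doublets, dtype=bool)]
    )
    parent_rows = np.vstack([truth.doublet_parents, parents])
    new_truth = TruthLabels(
        population=population,
        is_doublet=is_doublet,
        is_contaminant=is_contaminant,
        markers=truth.markers,
        doublet_parents=parent_rows,
    )
    return (
        CountMatrix(values, barcodes, list(counts.gene_ids), counts.species),
        new_truth,
    )


def make_species_panel(
    spec: SpeciesPanelSpec,
) -> list[tuple[CountMatrix, TruthLabels, pd.DataFrame]]:
    """Replicate one atlas across species with per-species expression shifts.

    All species share the population structure and marker assignment of
    ``spec.base``; each non-reference species applies an independent
    log-normal per-gene mean shift of sd ``species_shift_sd``.  Gene ids are
    species-local; each ortholog map is a strictly 1:1 two-column table
    (source gene id -> reference gene id) covering ``ortholog_coverage`` of
    the genes.
    """
    master = np.random.default_rng(spec.base.seed)
    ref_gene_ids, pop_names, means, contam_mu, markers = _population_means(
        spec.base, master
    )
    child_seeds = master.integers(0, 2**31 - 1, size=2 * spec.n_species)

    out = []
    for s in range(spec.n_species):
        species = f"species_{s}"
        rng = np.random.default_rng(child_seeds[2 * s])
        shift = (
            np.ones(spec.base.n_genes)
            if s == 0 or spec.species_shift_sd == 0
            else rng.lognormal(0.0, spec.species_shift_sd, size=spec.base.n_genes)
        )
        base = spec.base
        frac = base.frac_contaminant_cells
        n_singlets = base.n_populations * base.cells_per_population
        n_contam = int(round(n_singlets * frac / (1.0 - frac))) if frac > 0 else 0
        pops = np.repeat(pop_names, base.cells_per_population)
        pops = np.concatenate([pops, np.repeat("NonNeuronal", n_contam)])
        factors = _libsize_factors(rng, len(pops), base.libsize_cv)
        rows = []
        for i, pop in enumerate(pops):
            mu = contam_mu if pop == "NonNeuronal" else means[pop]
            rows.append(_nb_draw(rng, factors[i] * mu * shift, base.dispersion))
        values = sp.csr_matrix(np.vstack(rows))

        if spec.gene_rename_scheme == "prefix":
            local_ids = [f"{species}:{g}" for g in ref_gene_ids]
        else:
            local_ids = list(ref_gene_ids)
        barcodes = [f"{species}-cell-{i:05d}" for i in range(len(pops))]
        truth = TruthLabels(
            population=pops,
            is_doublet=np.zeros(len(pops), dtype=bool),
            is_contaminant=(pops == "NonNeuronal"),
            markers={k: v for k, v in markers.items() if k != "NonNeuronal"},
        )
        map_rng = np.random.default_rng(child_seeds[2 * s + 1])
        n_cov = int(round(spec.ortholog_coverage * base.n_genes))
        keep = np.sort(map_rng.choice(base.n_genes, size=n_cov, replace=False))
        ortholog_map = pd.DataFrame(
            {
                "source_id": [local_ids[i] for i in keep],
                "reference_id": [ref_gene_ids[i] for i in keep],
            }
        )
        out.append(
            (CountMatrix(values, barcodes, local_ids, species), truth, ortholog_map)
        )
    return out


def make_trap_experiment(
    spec: TrapSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate paired bead/sup NB counts with planted effects.

    Returns ``(counts, metadata, truth)``: counts is genes x samples;
    metadata has one row per sample with pair id, fraction (bead/sup),
    genotype and treatment; truth lists the planted enriched and
    leptin-responsive gene sets with signed effect sizes.  Genotype and
    treatment are balanced across pairs so both regression designs are
    identifiable.  Enrichment elevates bead over sup; the leptin effect
    applies only to bead samples of leptin-treated pairs.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = _gene_ids(spec.n_genes)
    sigma = 1.0
    base = spec.baseline_mean * rng.lognormal(-(sigma**2) / 2, sigma, spec.n_genes)

    n_enr = int(round(spec.frac_enriched * spec.n_genes))
    n_lep = int(round(spec.frac_leptin_responsive * spec.n_genes))
    perm = rng.permutation(spec.n_genes)
    enriched_idx = np.sort(perm[:n_enr])
    leptin_idx = np.sort(perm[n_enr : n_enr + n_lep])
    leptin_sign = rng.choice([-1, 1], size=n_lep)

    pair_factor = rng.lognormal(0.0, 0.3, size=spec.n_pairs)
    genotype = [spec.genotypes[i % 2] for i in range(spec.n_pairs)]
    treatment = ["PBS" if (i // 2) % 2 == 0 else "leptin" for i in range(spec.n_pairs)]

    samples, meta_rows, cols = [], [], []
    enr_fold = 2.0**spec.enrichment_log2fc
    lep_fold = 2.0 ** (leptin_sign * spec.leptin_log2fc)
    for p in range(spec.n_pairs):
        for fraction in ("bead", "sup"):
            mu = base * pair_factor[p]
            if fraction == "bead":
                mu = mu.copy()
                mu[enriched_idx] *= enr_fold
                if treatment[p] == "leptin":
                    mu[leptin_idx] *= lep_fold
            samples.append(f"pair{p + 1}_{fraction}")
            meta_rows.append(
                {
                    "sample": samples[-1],
                    "pair": f"pair{p + 1}",
                    "fraction": fraction,
                    "genotype": genotype[p],
                    "treatment": treatment[p],
                }
            )
            cols.append(_nb_draw(rng, mu, spec.dispersion))

    counts = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=samples)
    counts.index.name = "gene"
    metadata = pd.DataFrame(meta_rows)

    truth = pd.DataFrame({"gene": gene_ids})
    truth["enriched"] = np.isin(np.arange(spec.n_genes), enriched_idx)
    truth["enrichment_log2fc"] = np.where(
        truth["enriched"],
        spec.enrichment_log2fc if spec.enrichment_log2fc != 0 else 0.0,
        0.0,
    )
    truth["leptin_responsive"] = np.isin(np.arange(spec.n_genes), leptin_idx)
    lep_lfc = np.zeros(spec.n_genes)
    lep_lfc[leptin_idx] = leptin_sign * spec.leptin_log2fc
    truth["leptin_log2fc"] = lep_lfc if spec.leptin_log2fc != 0 else 0.0
    # zero-effect specs plant nothing
    if spec.enrichment_log2fc == 0:
        truth["enriched"] = False
    if spec.leptin_log2fc == 0:
        truth["leptin_responsive"] = False
    return counts, metadata, truth


def spec_to_json(spec) -> dict:
    """Serializable view of any generator spec (for fixture provenance)."""
    d = asdict(spec)
    return d
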