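# Methods

This note documents the models behind `leprmap`, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Synthetic data model

All generators draw counts from a negative binomial parameterized by mean
`m` and dispersion `phi` (variance `m + phi·m²`), sampled as a
gamma–Poisson mixture from a single `numpy` Generator stream per call, so
every output is bit-reproducible given its spec and seed.

**Atlas.** Background gene means are log-normal around `baseline_mean`
(sigma 0.5 on the log scale, mean-preserving); per-cell library-size
factors are log-normal with mean 1 and CV `libsize_cv`. Each population
receives a disjoint block of `markers_per_population` marker genes.
Marker genes sit at a low off-population baseline (0.1 × `baseline_mean`,
without the log-normal tail) and are elevated by `2^marker_log2fc` inside
their population — mimicking curated markers, which are reliably expressed
in their population and near-silent elsewhere. This makes the ratio of
in- to out-population marker means exactly the nominal fold change while
keeping detection fractions in the regime the marker tests assume
(fraction-in ≈ 0.5, fraction-out ≈ 0.1 at the defaults). Contaminant
("nonneuronal") cells draw from an independent permuted profile plus a
block of distinctive pseudo-genes. Defaults — 6 populations × 300 cells,
2,000 genes, 40 markers per population at log2FC 3, dispersion 0.2,
library CV 0.3, `baseline_mean` 1.0 — give nuclei a median of ~1,100
detected genes, so nearly all pass the 600-gene threshold, as in real
hypothalamic nucleus preparations where the threshold trims only a small
tail.

**Doublets** are exact element-wise sums of two distinct sampled cells,
appended at the requested rate; truth records the parent rows.

**Species panels** share one atlas model across species; each
non-reference species multiplies every gene mean by an independent
log-normal factor (sd `species_shift_sd`) and renames genes into a
species-local namespace. Each species' ortholog map is a strictly 1:1
random subset covering `ortholog_coverage` of genes, drawn independently
per species, so the combined analysis sees the realistic intersection
(~64% of genes at 80% coverage for two species).

**TRAP experiments** generate complete bead/sup pairs with log-normal
pair-specific baselines (sd 0.3). Genotype and treatment alternate across
pairs so both regression designs stay identifiable. Enriched genes are
elevated in bead samples by `enrichment_log2fc`; leptin-responsive genes
shift by ±`leptin_log2fc` only in bead samples of leptin-treated pairs.
The enrichment benchmarks use 4 pairs; the leptin-response benchmarks use
12 pairs (3 bead samples per genotype × treatment cell), the canonical
minimum replication for a two-factor bulk design.

**Not emulated:** ambient-RNA soup, UMI saturation, batch chemistry
effects, cell-cycle or activity-state gradients within populations, and
doublet-specific capture biases. Passing tests therefore demonstrate that
the algorithms implement their contracts under the stated noise model,
not that real tissue meets these assumptions.

## QC and doublet scoring

Gene and cell retention is a single pass — genes detected in ≥ 5 cells
first, then cells with ≥ 600 detected genes among retained genes — with
every count logged so the retention waterfall is auditable. "At least"
thresholds are inclusive (≥). A pathological matrix could in principle
need a second pass to re-stabilize (removing cells can drop a gene below
5 cells); the filter deliberately performs the one pass the rule
describes, and is empirically idempotent on realistic data.

The doublet scorer simulates `sim_ratio` (default 2.0) synthetic doublets
per observed cell as sums of random observed pairs, log-normalizes and
standardizes the union matrix, embeds it in 30 PCs, and computes for each
observed cell the fraction `q` of simulated doublets among its nearest
neighbors (neighborhood size `0.5·√n·(1 + sim_ratio)`). The score is the
excess enrichment over chance, `clip((q − ρ)/(1 − ρ), 0, 1)` with
`ρ = n_sim/(n_sim + n)`: a neighborhood no more simulated-rich than
chance scores 0 and a purely simulated one scores 1. Removal follows the
cluster-median rule: all cells of any provisional cluster (one Leiden
pass at resolution 1.0) with median score > 0.3 are removed, then any
remaining cell with score > 0.3; both comparisons are strict. Homotypic
doublets (same-population parents, ~1/6 of random pairs at 6 equal
populations) are only partially detectable by any simulated-doublet
method, since they resemble deeper-sequenced singlets; at the default
conditions the rule removes ~85% of doublets at < 1% singlet loss.

## Normalization and embedding

Pooled size factors use a single-pass ring-pool deconvolution: cells are
ordered randomly on a ring, each window of 20 cells yields one equation
(sum of member factors ≈ median ratio of the pooled profile to the mean
cell profile), and the sparse system is solved by least squares with
low-weight library-size anchors (weight 0.1) that fix the overall scale
and the tiny-n case. Factors are normalized to mean 1. A pure
library-size mode is available; both satisfy the closed-form checks
(identical cells → factors 1; a 2× scalar cell → factor ratio 2:1).

Variable genes are ranked by standardized variance: a quadratic trend of
log10 variance on log10 mean is fit across expressed genes, per-value
z-scores against the trend are clipped at √n, and genes are ordered by
the variance of the clipped z-scores, with lexicographic gene-id
tie-breaks. Defaults: 2,000 genes, scaling clip ±10.

PCA retains the smallest k in [15, 30] at which the scree curve has
flattened — the relative drop `(vf[k] − vf[k+1])/vf[k]` falls below 1e-3,
a vanished fraction counting as flat — else 30. A relative criterion is
used because variance fractions scale as 1/n_genes: an absolute
difference threshold would spuriously "flatten" any high-dimensional
dataset, including pure noise. Component signs are fixed by making the
largest-magnitude loading positive. The elbow rule automates a judgment
call that is usually made by eye; both bounds and the tolerance are
configurable.

## Clustering and naming

The SNN graph connects cells whose kNN sets (k = 20, self included)
overlap, weighted by Jaccard similarity and pruned below 1/15. Leiden
modularity optimization (RB-configuration, seeded, via `leidenalg`) is
run at resolutions 0.2, 0.4, …; the scan stops once the running maximum
mean silhouette has not improved for 2 consecutive steps (or at
resolution 3.0) and returns the argmax over all evaluated points. The
silhouette is computed on the retained PCs with Euclidean distance,
subsampled to ≤ 5,000 cells with a fixed seed; a one-cluster partition
scores −∞ and is only returned (with a warning) if nothing else exists.

Markers are one-vs-rest Wilcoxon rank-sum tests on log-normalized
expression, restricted to genes detected in ≥ 25% of the cluster with
|log2FC| ≥ 0.25 (fold changes on expm1 means with pseudocount 1), with BH
correction within each cluster. A *unique* marker is significant (FDR
< 0.05), positively changed, and detected outside its cluster in ≤ 10% of
cells, in exactly one cluster; clusters take their highest-log2FC unique
marker as their name (ties lexicographic). Clusters without a unique
marker are classified GABAergic or glutamatergic by comparing mean
expression of the inhibitory (`Slc32a1`) and excitatory (`Slc17a6`)
indicator genes and numbered in dendrogram order — `GABA`, `GABA2`, … and
`GLU1`, `GLU2`, … — falling back to `UNK-n` when indicators are absent
from the panel.

## Label projection

Query and reference are scaled on the reference's variable genes within
the shared gene set; the joint embedding is the SVD of their
cross-product (query left singular vectors, reference right), rows
L2-normalized. Dimensions are capped at twice the number of reference
types, because the cross-covariance between two datasets sharing T
populations has rank ≈ T and additional dimensions only inject noise into
the neighbor structure. Each query cell scores each type by the mean
similarity `1/(1 + d)` of that type's cells among its 20 nearest
reference cells; the assigned label maximizes the score summed over the
cell and its 14 nearest query-side neighbors (15-cell vote, ties by
lexicographic type name), and the vote fraction reports how many of the
15 agreed. Nonneuronal removal keeps cells whose assigned type is in the
configured neuronal whitelist.

## Cross-species conservation

Ortholog restriction keeps only mapped genes (maps must be strictly 1:1)
and renames them into the reference namespace. Harmonization first
removes each species' global mean offset in PC space — exact for a pure
between-species shift — then iterates a soft k-means (k ≈ n/30, capped at
20; bandwidth set to the median nearest-center distance) with per-cluster
centroid matching: each cell moves by the responsibility-weighted offsets
of its species' cluster centroids from the global ones, until the largest
displacement falls below 1e-3 of the embedding RMS norm (≤ 10
iterations). Harmonization never changes cell count or dimensionality.
The contract is behavioral — between-species gaps shrink, neighbor
batch-mixing entropy rises, within-population structure survives — rather
than equivalence to any particular tool.

Conserved matching assigns each reference population to the combined
cluster holding its largest cell share if that share is ≥ 0.8 (the
fraction is of the *population's* cells, and the comparison is inclusive;
both configurable). When two or more populations claim the same combined
cluster, that cluster is subclustered (a fresh resolution scan on its
cells, forced past one cluster if needed) and each contested population
goes to the subcluster holding the most of its cells; exact plurality
ties go to the larger population, then lexicographically, and a
population that loses all its subclusters is left unmatched. Populations
never reaching the threshold are "unmatched"; unassigned clusters keep
their numeric ids.

## TRAP differential expression and the association score

Counts are normalized by median-of-ratios size factors (library-size
geometric mean as fallback when no gene is all-positive) entering the GLM
as offsets. Two designs: `~ pair + fraction` over all samples (testing
the bead coefficient; pairs must be complete) and
`~ genotype + treatment` over bead samples only (testing the leptin
coefficient). Rank-deficient designs are rejected.

Dispersions are estimated under the design: a per-gene Poisson fit
provides means, the Pearson-residual method-of-moments estimate (scaled
by n/(n−p)) is bounded within 8× of a parametric trend
`phi(mu) = a0 + a1/mu`, and shrunk toward the trend in log space with an
empirical-Bayes weight. The trend's prior df comes from the excess spread
of raw log-dispersions around it beyond the ~2/(n−p) sampling variance
(capped at 200): when gene dispersions genuinely follow the trend,
shrinkage is strong and the effective df is large. Wald statistics on the
tested coefficient are referred to a Student t with residual-plus-prior
df — with 3 residual df a normal reference is badly anticonservative in
the tail. BH correction runs across genes with mean normalized count
≥ 1. Under the global-null simulation the FDR < 0.05 fraction is ~0, and
planted 4-fold enrichment at dispersion 0.1 with 4 pairs is detected with
power ≥ 0.9.

The leptin signature is the set of genes at FDR < alpha (default 0.05,
the conventional choice) signed by the direction of the leptin
coefficient. The
association score restricts the scaled single-cell matrix to signature
genes, computes PC1 over cells, and aligns its sign so the sum of
loading × signature-sign is positive; the per-cell score is the PC1
coordinate (reported both signed — the default headline — and as
magnitude, since "the magnitude of the first principal component" admits
both readings), aggregated per population by the mean over member cells
(pseudobulk aggregation is a straightforward variant the caller can apply
to population means). Scores are invariant to signature gene order and to
non-signature genes.

## Problem sizes and runtime

The bundled benchmarks run the full study conditions at desk scale: the
1,980-cell atlas for clustering and doublet benchmarks, a 3,000-cell
split atlas for label transfer, a 2,400-cell two-species panel, and
2,000-gene TRAP tables. The complete acceptance run takes about one
minute on a single CPU; the test suite about ninety seconds.

## Known limitations

- The doublet scorer shares the intrinsic blind spot of
  simulated-doublet methods for homotypic doublets.
- The single-pass pooled size-factor scheme lacks the multi-pool-size
  robustness of full deconvolution implementations; heavily imbalanced
  compositions may prefer the library mode.
- Harmonization's global centering assumes batches share overall
  composition; strongly composition-biased batches would be
  over-corrected.
- The NB Wald test with few residual df leans on the dispersion-trend
  prior; datasets whose dispersions genuinely scatter far from any trend
  will see reduced moderation and more conservative inference.
- The marker pre-filter (detection fraction and fold change) selects
  genes on the same data the rank-sum test uses, so per-selected-gene
  p-values are optimistic under the null — the false-discovery guarantee
  is over the gene panel, not the filtered subset.
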