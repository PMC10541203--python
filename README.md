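# leprmap

Mapping hypothalamic LepRb neuron populations from single-nucleus RNA-seq.

Leptin acts on hypothalamic neurons that express the long form of the
leptin receptor (LepRb) to regulate energy balance, but LepRb cells are a
heterogeneous mixture of neuron populations. `leprmap` is a tested,
reusable implementation of the computational pipeline used to discover
and characterize those populations:

- **QC and doublet removal** — genes detected in ≥ 5 cells and cells with
  ≥ 600 detected genes are retained; doublets are scored by a
  simulated-doublet kNN method (synthetic doublets = sums of random
  observed cell pairs, co-embedded in PC space; the score is the excess of
  simulated doublets in a cell's neighborhood over chance) and removed
  when a cluster's median score or a cell's own score exceeds 0.3.
- **Embedding** — pooled size-factor normalization (single-pass ring-pool
  deconvolution), standardized-variance variable-gene selection, per-gene
  scaling with clipping, and PCA with an automatic scree-elbow rule that
  retains 15–30 components.
- **Clustering** — Leiden community detection on a shared-nearest-neighbor
  (Jaccard) graph, with the resolution parameter scanned from 0.2 upward
  in steps of 0.2 until the mean silhouette score (Euclidean, PC space) is
  maximal; clusters are ordered by average-linkage hierarchical clustering
  of their centroids, markers found by one-vs-rest Wilcoxon rank-sum tests
  (BH-corrected), and populations named by their top unique marker or, in
  its absence, their neurochemical identity (GABA vs GLU by indicator-gene
  expression).
- **Reference label projection** — a CCA-style joint embedding (SVD of the
  scaled cross-product) followed by a 15-cell vote: each cell takes the
  type with the highest summed score over itself and its 14 nearest
  neighbors; nonneuronal cells are then dropped against a whitelist.
- **Cross-species conservation** — species matrices are restricted to
  strictly 1:1 orthologs, harmonized with a soft-cluster centroid
  correction, and co-clustered; a combined cluster absorbing ≥ 80% of a
  reference population's cells inherits its name, with contested clusters
  resolved by subclustering and plurality assignment.
- **TRAP-seq leptin response** — per-gene negative-binomial GLMs with
  median-of-ratios size factors and trend-shrunk dispersions fit the
  bead/sup enrichment design (`~ pair + fraction`) and the leptin design
  (`~ genotype + treatment`, bead samples only); significant
  leptin-regulated genes form a signed signature, and cells are scored by
  their projection onto the first principal component of the scaled
  signature-gene expression (the association score).

A first-class synthetic-data module (`leprmap.synthetic`) generates every
input with known ground truth — negative-binomial atlases with planted
markers and contaminants, doublets as exact parent sums, multi-species
replicas with partial ortholog maps, and paired bead/sup TRAP counts with
planted enrichment and leptin effects — so every stage is testable at desk
scale.

## Worked example

```bash
python analysis/01_simulate_atlas.py --seed 1     # synthetic atlas + doublets
python analysis/02_qc_and_cluster.py --seed 1     # QC -> clustering -> naming
```

prints (abridged):

```
wrote 1980 cells (180 doublets) x 2000 genes to results/atlas
QC waterfall:
  input_cells: 1980
  cells_after_cell_filter: 1970
  cells_after_doublet_filter: 1798
selected resolution 0.2 -> 6 clusters, mean silhouette 0.196
cluster names: {0: 'G0151', 1: 'G0087', 2: 'G0070', 3: 'G0183', 4: 'G0232', 5: 'G0001'}
ARI vs generator truth (retained cells): 0.981
```

Reading the output: of 1,980 input nuclei, 1,970 pass the 600-gene
threshold and 1,798 survive doublet removal (the 172 discarded cells are
dominated by the 180 injected doublets, at under 1% singlet loss). The resolution scan
selects 6 clusters whose mean silhouette is maximal over the grid; every
cluster is named by one of its planted marker genes, and the partition
agrees with the generator's ground truth at an adjusted Rand index of
0.98. The remaining drivers run label projection
(`analysis/03_label_transfer.py`), cross-species conserved matching
(`analysis/04_cross_species.py`), and TRAP differential expression plus
association scoring (`analysis/05_trap_de_and_signature.py`).

The same pipeline is scriptable on real 10x-style count directories via
the CLI:

```bash
leprmap run --config cfg.json          # full pipeline from a JSON config
leprmap simulate --spec spec.json --out fixtures/atlas
leprmap score --signature sig.tsv --counts fixtures/atlas
```

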