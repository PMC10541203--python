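"""Generator contracts: determinism, NB moments, planted structure."""

import numpy as np
import pytest
import scipy.sparse as sp

from leprmap.containers import ConfigurationError, CountMatrix
from leprmap.synthetic import (
    AtlasSpec,
    SpeciesPanelSpec,
    TrapSpec,
    TruthLabels,
    inject_doublets,
    make_atlas,
    make_species_panel,
    make_trap_experiment,
)


class TestMakeAtlas:
    def test_deterministic_given_seed(self):
        spec = AtlasSpec(n_populations=2, cells_per_population=30, n_genes=100, seed=5)
        a, _ = make_atlas(spec)
        b, _ = make_atlas(spec)
        assert (a.values != b.values).nnz == 0
        assert a.barcodes == b.barcodes

    def test_marker_fold_change_matches_model(self):
        """Sample marker means exceed non-member means by ~2^log2fc."""
        spec = AtlasSpec(
            n_populations=3,
            cells_per_population=600,
            n_genes=300,
            markers_per_population=20,
            marker_log2fc=3.0,
            libsize_cv=0.0,
            seed=11,
        )
        counts, truth = make_atlas(spec)
        dense = counts.values.toarray()
        gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
        for pop, genes in truth.markers.items():
            cols = [gene_index[g] for g in genes]
            inside = dense[np.ix_(truth.population == pop, cols)].mean()
            outside = dense[np.ix_(truth.population != pop, cols)].mean()
            assert inside / outside == pytest.approx(8.0, rel=0.10)

    def test_nb_mean_variance_relation(self):
        """Empirical variance tracks mean + dispersion * mean^2."""
        phi = 0.3
        spec = AtlasSpec(
            n_populations=1,
            cells_per_population=1000,
            n_genes=200,
            markers_per_population=0,
            baseline_mean=5.0,
            dispersion=phi,
            libsize_cv=0.0,
            seed=3,
        )
        counts, _ = make_atlas(spec)
        x = counts.values.toarray().astype(float)
        mean = x.mean(axis=0)
        var = x.var(axis=0, ddof=1)
        expected = mean + phi * mean**2
        # regression through the expected relation, pooled over genes
        ratio = np.median(var / expected)
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_contaminant_cells_flagged_and_distinct(self):
        spec = AtlasSpec(
            n_populations=3,
            cells_per_population=50,
            n_genes=300,
            markers_per_population=20,
            frac_contaminant_cells=0.2,
            seed=9,
        )
        counts, truth = make_atlas(spec)
        frac = truth.is_contaminant.mean()
        assert frac == pytest.approx(0.2, abs=0.02)
        assert set(truth.population[truth.is_contaminant]) == {"NonNeuronal"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            AtlasSpec(n_populations=10, n_genes=50, markers_per_population=10)
        with pytest.raises(ConfigurationError):
            AtlasSpec(baseline_mean=0.0)
        with pytest.raises(ConfigurationError):
            AtlasSpec(frac_contaminant_cells=1.0)

    def test_marker_lists_disjoint(self, small_atlas):
        _, truth = small_atlas
        seen = set()
        for genes in truth.markers.values():
            assert not seen & set(genes)
            seen |= set(genes)


class TestInjectDoublets:
    def test_rate_zero_is_identity(self, small_atlas):
        counts, truth = small_atlas
        out, out_truth = inject_doublets(counts, truth, 0.0, seed=1)
        assert out is counts and out_truth is truth

    def test_doublet_count_is_exact(self, small_atlas):
        counts, truth = small_atlas
        out, out_truth = inject_doublets(counts, truth, 0.1, seed=1)
        assert out.n_cells == counts.n_cells + round(0.1 * counts.n_cells)
        assert out_truth.is_doublet.sum() == round(0.1 * counts.n_cells)

    def test_doublet_rows_are_exact_parent_sums(self, small_atlas):
        counts, truth = small_atlas
        out, out_truth = inject_doublets(counts, truth, 0.05, seed=2)
        dense = out.values.toarray()
        for i in np.flatnonzero(out_truth.is_doublet):
            p, q = out_truth.doublet_parents[i]
            assert (dense[i] == dense[p] + dense[q]).all()

    def test_two_cell_sum_definition(self):
        values = sp.csr_matrix(np.array([[1, 2], [3, 0]]))
        cm = CountMatrix(values, ["a", "b"], ["g1", "g2"])
        truth = TruthLabels(
            population=np.array(["P1", "P1"]),
            is_doublet=np.zeros(2, bool),
            is_contaminant=np.zeros(2, bool),
        )
        out, _ = inject_doublets(cm, truth, 0.5, seed=0)
        assert out.values.toarray()[-1].tolist() == [4, 2]

    def test_rate_out_of_range(self, small_atlas):
        counts, truth = small_atlas
        with pytest.raises(ConfigurationError):
            inject_doublets(counts, truth, 0.6, seed=0)


class TestSpeciesPanel:
    def test_ortholog_maps_cover_and_are_unique(self):
        base = AtlasSpec(
            n_populations=2, cells_per_population=20, n_genes=1000,
            markers_per_population=10, seed=4,
        )
        panel = make_species_panel(
            SpeciesPanelSpec(base=base, n_species=2, ortholog_coverage=0.8)
        )
        assert len(panel) == 2
        for counts, truth, omap in panel:
            assert len(omap) == 800
            assert omap["source_id"].is_unique and omap["reference_id"].is_unique
            assert set(truth.population) == {"P1", "P2"}
            assert set(omap["source_id"]) <= set(counts.gene_ids)

    def test_zero_shift_species_share_model(self):
        base = AtlasSpec(
            n_populations=2, cells_per_population=400, n_genes=200,
            markers_per_population=10, libsize_cv=0.0, seed=6,
        )
        panel = make_species_panel(
            SpeciesPanelSpec(
                base=base, n_species=2, ortholog_coverage=1.0, species_shift_sd=0.0
            )
        )
        means = [c.values.toarray().mean(axis=0) for c, _, _ in panel]
        # iid replicas of the same model: per-gene means agree within noise
        assert np.corrcoef(means[0], means[1])[0, 1] > 0.99

    def test_panel_deterministic(self):
        spec = SpeciesPanelSpec(
            base=AtlasSpec(n_populations=2, cells_per_population=15, n_genes=80,
                           markers_per_population=5, seed=8)
        )
        a = make_species_panel(spec)
        b = make_species_panel(spec)
        for (ca, _, ma), (cb, _, mb) in zip(a, b):
            assert (ca.values != cb.values).nnz == 0
            assert ma.equals(mb)


class TestTrapExperiment:
    def test_planted_effect_counts(self):
        counts, meta, truth = make_trap_experiment(
            TrapSpec(n_pairs=4, n_genes=2000, frac_enriched=0.1, seed=2)
        )
        assert truth["enriched"].sum() == 200
        assert counts.shape == (2000, 8)
        grouped = meta.groupby("pair")["fraction"].agg(set)
        assert all(g == {"bead", "sup"} for g in grouped)

    def test_zero_effect_spec_plants_nothing(self):
        _, _, truth = make_trap_experiment(
            TrapSpec(enrichment_log2fc=0.0, leptin_log2fc=0.0, seed=3)
        )
        assert not truth["enriched"].any()
        assert not truth["leptin_responsive"].any()
        assert (truth["leptin_log2fc"] == 0).all()

    def test_deterministic(self):
        spec = TrapSpec(seed=12)
        a = make_trap_experiment(spec)
        b = make_trap_experiment(spec)
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_single_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            TrapSpec(n_pairs=1)
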