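"""NB GLM differential expression, signatures, association scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from leprmap.synthetic import TrapSpec, make_trap_experiment
from leprmap.trap import (
    DesignSpec,
    Signature,
    build_signature,
    fit_nb_de,
    score_signature,
)


@pytest.fixture(scope="module")
def null_experiment():
    """Six complete pairs with no planted effects."""
    return make_trap_experiment(
        TrapSpec(n_pairs=6, n_genes=400, enrichment_log2fc=0.0,
                 leptin_log2fc=0.0, seed=31)
    )


class TestFitNbDe:
    def test_well_measured_null_gene_shows_no_effect(self):
        """Identical bead/sup means, 6 pairs: a well-measured gene (mean
        500, dispersion 0.01) is called null in >= 90% of 200 replicates."""
        rng = np.random.default_rng(91)
        mu, phi, n_pairs, n_rep = 500.0, 0.01, 6, 200
        lam = rng.gamma(1 / phi, mu * phi, size=(n_rep, 2 * n_pairs))
        counts = pd.DataFrame(
            rng.poisson(lam),
            index=[f"g{i}" for i in range(n_rep)],
            columns=[f"pair{p}_{f}" for p in range(n_pairs) for f in ("bead", "sup")],
        )
        meta = pd.DataFrame(
            {
                "sample": counts.columns,
                "pair": [c.split("_")[0] for c in counts.columns],
                "fraction": [c.split("_")[1] for c in counts.columns],
            }
        )
        de = fit_nb_de(counts, meta, "pair+fraction")
        calm = ((de["log2fc"].abs() < 0.2) & (de["p"] > 0.05)).mean()
        assert calm >= 0.9

    def test_null_experiment_p_values_not_anticonservative(self, null_experiment):
        counts, meta, _ = null_experiment
        de = fit_nb_de(counts, meta, "pair+fraction")
        tested = de.dropna(subset=["p"])
        assert (tested["p"] < 0.05).mean() <= 0.08
        assert not (tested["fdr"] < 0.05).any()

    def test_planted_enrichment_detected(self, trap_data):
        counts, meta, truth = trap_data
        de = fit_nb_de(counts, meta, "pair+fraction")
        enriched = truth.set_index("gene")["enriched"]
        hits = (de["fdr"] < 0.05).fillna(False)
        assert hits[enriched].mean() >= 0.9  # power
        lfc = de.loc[enriched[enriched].index, "log2fc"]
        assert lfc.median() == pytest.approx(2.0, abs=0.3)

    def test_incomplete_pairs_rejected(self, trap_data):
        counts, meta, _ = trap_data
        broken = meta.drop(index=0)
        with pytest.raises(ValueError, match="pairs"):
            fit_nb_de(counts[broken["sample"]], broken, "pair+fraction")

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec("fraction-only")

    def test_agrees_with_deseq2_oracle(self):
        """Independent cross-check of fold changes against pyDESeq2."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, meta, truth = make_trap_experiment(
            TrapSpec(n_pairs=4, n_genes=150, seed=77)
        )
        de = fit_nb_de(counts, meta, "pair+fraction")

        adata_counts = counts.T
        clinical = meta.set_index("sample").loc[adata_counts.index]
        dds = DeseqDataSet(
            counts=adata_counts.astype(int),
            metadata=clinical[["pair", "fraction"]],
            design="~pair + fraction",
            quiet=True,
        )
        dds.deseq2()
        res = DeseqStats(
            dds, contrast=["fraction", "sup", "bead"], quiet=True
        )
        res.summary()
        oracle_lfc = -res.results_df["log2FoldChange"]  # orient bead vs sup

        both = de.join(oracle_lfc.rename("oracle"), how="inner").dropna()
        r = np.corrcoef(both["log2fc"], both["oracle"])[0, 1]
        assert r > 0.95
        enriched = truth.set_index("gene")["enriched"].loc[both.index]
        # both routes see the planted enrichment the same way
        assert both.loc[enriched, "log2fc"].median() == pytest.approx(
            both.loc[enriched, "oracle"].median(), abs=0.25
        )


class TestBuildSignature:
    def test_empty_signature_is_an_error(self, null_experiment):
        counts, meta, _ = null_experiment
        de = fit_nb_de(counts, meta, "genotype+treatment")
        with pytest.raises(ValueError, match="alpha"):
            build_signature(de, alpha=1e-12)

    def test_recovers_planted_leptin_genes_with_signs(self):
        counts, meta, truth = make_trap_experiment(TrapSpec(n_pairs=12, seed=13))
        de = fit_nb_de(counts, meta, "genotype+treatment")
        sig = build_signature(de, alpha=0.05)
        planted = set(truth[truth["leptin_responsive"]]["gene"])
        recall = len(set(sig.genes) & planted) / len(planted)
        precision = len(set(sig.genes) & planted) / len(sig.genes)
        assert recall >= 0.8
        assert precision >= 0.9
        planted_sign = truth.set_index("gene")["leptin_log2fc"]
        for g, s in zip(sig.genes, sig.signs):
            if g in planted:
                assert s == np.sign(planted_sign[g])


class TestScoreSignature:
    def _gradient_fixture(self, rng):
        """Two perfectly correlated up-genes along a 1-D gradient."""
        grad = np.linspace(-2, 2, 100)
        mat = np.column_stack([grad, grad, rng.normal(0, 1, 100)])
        mat = (mat - mat.mean(0)) / mat.std(0)
        return mat, ["up1", "up2", "noise"], grad

    def test_gradient_rank_preserved(self, rng):
        mat, genes, grad = self._gradient_fixture(rng)
        sig = Signature(genes=["up1", "up2"], signs=np.array([1, 1]))
        res = score_signature(mat, genes, sig)
        np.testing.assert_array_equal(
            np.argsort(res.per_cell), np.argsort(grad)
        )

    def test_gene_order_invariance_exact(self, rng):
        mat, genes, _ = self._gradient_fixture(rng)
        a = score_signature(mat, genes, Signature(["up1", "up2"], np.array([1, 1])))
        b = score_signature(mat, genes, Signature(["up2", "up1"], np.array([1, 1])))
        np.testing.assert_array_equal(a.per_cell, b.per_cell)

    def test_non_signature_genes_irrelevant(self, rng):
        mat, genes, _ = self._gradient_fixture(rng)
        sig = Signature(["up1", "up2"], np.array([1, 1]))
        full = score_signature(mat, genes, sig)
        trimmed = score_signature(mat[:, :2], genes[:2], sig)
        np.testing.assert_allclose(full.per_cell, trimmed.per_cell, atol=1e-12)

    def test_graded_populations_rank_exactly(self, rng):
        grades = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        signs = rng.choice([-1, 1], 20)
        pops = np.repeat([f"pop{i}" for i in range(5)], 80)
        expr = np.repeat(grades, 80)[:, None] * signs[None, :]
        expr = expr + rng.normal(0, 0.4, expr.shape)
        mat = (expr - expr.mean(0)) / expr.std(0)
        genes = [f"S{i}" for i in range(20)]
        res = score_signature(mat, genes, Signature(genes, signs), pops)
        by_pop = res.per_population.set_index("population")["score"]
        scores = by_pop.loc[[f"pop{i}" for i in range(5)]].to_numpy()
        assert (np.argsort(scores) == np.argsort(grades)).all()
        assert spearmanr(scores, grades).statistic == pytest.approx(1.0)

    def test_zero_variance_signature_rejected(self):
        mat = np.ones((30, 2))
        with pytest.raises(ValueError):
            score_signature(mat, ["a", "b"], Signature(["a", "b"], np.array([1, 1])))
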