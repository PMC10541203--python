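"""Paired negative-binomial differential expression and leptin scoring.

TRAP-seq counts are modeled per gene with a negative-binomial GLM
(log link, median-of-ratios size factors as offsets).  Two designs are
supported: bead-vs-sup enrichment with a sample-pair effect
(``~ pair + fraction``), and the leptin response on bead samples only
(``~ genotype + treatment``).  Per-gene dispersions are method-of-moments
estimates shrunk toward a fitted mean-dispersion trend; the condition
coefficient gets a Wald test and BH correction across genes above a mean
normalized count floor.

Significant leptin-regulated genes form a signed signature; single-cell
association scores are the projection of scaled expression of those genes
onto their first principal component, sign-aligned with the signature so
higher scores mean a stronger leptin-like response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "Signature",
    "fit_nb_de",
    "build_signature",
    "score_signature",
]

LN2 = np.log(2.0)


@dataclass
class DesignSpec:
    """Which regression design to fit and which coefficient to test.

    ``kind`` is "pair+fraction" (bead-vs-sup enrichment over all samples)
    or "genotype+treatment" (leptin response, bead samples only).
    """

    kind: str = "pair+fraction"

    def __post_init__(self) -> None:
        if self.kind not in ("pair+fraction", "genotype+treatment"):
            raise ValueError(f"unknown design kind {self.kind!r}")


@dataclass
class Signature:
    """Signed leptin-response gene set: +1 up under leptin, -1 down."""

    genes: list[str]
    signs: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs must align")
        if len(self.genes) and not set(np.unique(self.signs)) <= {-1, 1}:
            raise ValueError("signs must be in {-1, +1}")


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.isfinite(log_counts).all(axis=1)
    if not finite.any():
        # no all-positive gene: fall back to library size
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.mean(np.log(totals)))
    log_geo = log_counts[finite].mean(axis=1)
    ratios = log_counts[finite] - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def _design_matrix(metadata: pd.DataFrame, design: DesignSpec):
    """Build (sample mask, design matrix, tested-column index)."""
    if design.kind == "pair+fraction":
        mask = np.ones(len(metadata), dtype=bool)
        meta = metadata
        pairs = sorted(meta["pair"].unique())
        # complete-pair check: the paired model needs each bead with its sup
        grp = meta.groupby("pair")["fraction"].agg(set)
        if not all(g == {"bead", "sup"} for g in grp):
            raise ValueError("pair+fraction design requires complete bead/sup pairs")
        cols = [np.ones(len(meta))]
        names = ["intercept"]
        for p in pairs[1:]:
            cols.append((meta["pair"] == p).to_numpy(float))
            names.append(f"pair_{p}")
        cols.append((meta["fraction"] == "bead").to_numpy(float))
        names.append("bead")
        tested = len(names) - 1
    else:
        mask = (metadata["fraction"] == "bead").to_numpy()
        meta = metadata[mask]
        cols = [np.ones(len(meta))]
        names = ["intercept"]
        genos = sorted(meta["genotype"].unique())
        for g in genos[1:]:
            cols.append((meta["genotype"] == g).to_numpy(float))
            names.append(f"genotype_{g}")
        cols.append((meta["treatment"] == "leptin").to_numpy(float))
        names.append("leptin")
        tested = len(names) - 1
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient (confounded columns)")
    return mask, x, tested, names


def _dispersion_estimates(
    k: np.ndarray, x: np.ndarray, offset: np.ndarray, base_mean: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-gene trend-shrunk dispersions estimated under the design.

    Fitted means come from a per-gene Poisson GLM on the full design, so
    real condition effects do not leak into the dispersion; the raw
    method-of-moments estimate from Poisson residuals is then shrunk (in
    log space) toward a parametric mean-dispersion trend a0 + a1/mu with
    an empirical-Bayes weight.  The prior df of the trend is estimated
    from the spread of raw log-dispersions around it (observed spread at
    the pure-sampling level means the trend explains everything and
    shrinkage is strong).  Returns (dispersions, prior_df).
    """
    n, p = x.shape
    dof_scale = n / max(n - p, 1)
    raw = np.full(k.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate genes may separate
        for g in range(k.shape[0]):
            y = k[g]
            if y.max() == 0:
                continue
            try:
                res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit(
                    maxiter=50
                )
                mu = np.clip(res.mu, 1e-8, None)
                num = float(((y - mu) ** 2 - mu).sum())
                raw[g] = dof_scale * num / float((mu**2).sum())
            except Exception:
                continue
    # parametric trend phi(mu) = a1 / mu + a0, fit on informative genes
    ok = np.isfinite(raw) & (raw > 1e-6) & (base_mean > 1)
    a0, a1 = 0.01, 1.0
    if ok.sum() >= 10:
        design = np.column_stack([np.ones(int(ok.sum())), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(design, raw[ok], rcond=None)
        a0 = max(float(coef[0]), 1e-4)
        a1 = max(float(coef[1]), 0.0)
    trend = np.clip(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-6, 10.0)
    # bound raw estimates within a factor of the trend (a noisy per-gene
    # moment estimate from few samples must not collapse the variance)
    raw_b = np.clip(np.where(np.isfinite(raw), raw, trend), trend / 8.0, trend * 8.0)

    # empirical-Bayes weight: sampling variance of a log moment estimate
    # is ~ 2 / residual_df; excess spread around the trend is real
    # gene-to-gene dispersion variation
    resid_df = max(n - p, 1)
    sampling_var = 2.0 / resid_df
    log_dev = np.log(raw_b[ok] / trend[ok]) if ok.any() else np.array([0.0])
    excess = max(float(np.var(log_dev)) - sampling_var, 0.0)
    prior_df = 2.0 / excess if excess > 1e-4 else 200.0
    prior_df = float(min(prior_df, 200.0))
    w = resid_df / (resid_df + prior_df)
    phi = np.exp(w * np.log(raw_b) + (1 - w) * np.log(trend))
    return np.where(np.isfinite(phi), phi, trend), prior_df


def fit_nb_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec | str = "pair+fraction",
    min_base_mean: float = 1.0,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test on the design's condition coefficient.

    ``counts`` is genes x samples with columns matching
    ``metadata['sample']``.  Returns a frame indexed by gene with columns
    log2fc, se, p, fdr, base_mean; genes with mean normalized count below
    ``min_base_mean`` are excluded from testing (NaN p/fdr).
    """
    if isinstance(design, str):
        design = DesignSpec(design)
    metadata = metadata.set_index("sample").loc[list(counts.columns)].reset_index()
    mask, x, tested, names = _design_matrix(metadata, design)
    k = counts.to_numpy(dtype=float)[:, mask]
    for lvl_col in range(x.shape[1]):
        if len(np.unique(x[:, lvl_col])) == 1 and lvl_col > 0:
            raise ValueError("design has a constant non-intercept column")
    if min((x[:, tested] == 1).sum(), (x[:, tested] == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per condition level")

    sf = _size_factors(k)
    offset = np.log(sf)
    base_mean = (k / sf).mean(axis=1)
    phi, prior_df = _dispersion_estimates(k, x, offset, base_mean)

    n_genes = k.shape[0]
    lfc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    testable = base_mean >= min_base_mean
    # moderated Wald reference: residual df plus the estimated prior df
    # of the dispersion trend (limma-style moderation)
    df_test = max(x.shape[0] - x.shape[1], 1) + prior_df
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate genes may separate
        for g in np.flatnonzero(testable):
            fam = sm.families.NegativeBinomial(alpha=float(phi[g]))
            try:
                res = sm.GLM(k[g], x, family=fam, offset=offset).fit(maxiter=100)
                beta, bse = res.params[tested], res.bse[tested]
                if not (np.isfinite(beta) and np.isfinite(bse) and bse > 0):
                    continue
                lfc[g] = beta / LN2
                se[g] = bse / LN2
                pval[g] = 2.0 * stats.t.sf(abs(beta / bse), df=df_test)
            except Exception:  # non-convergence on degenerate genes
                continue

    fdr = np.full(n_genes, np.nan)
    tested_mask = np.isfinite(pval)
    if tested_mask.any():
        fdr[tested_mask] = multipletests(pval[tested_mask], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "se": se,
            "p": pval,
            "fdr": fdr,
            "base_mean": base_mean,
        },
        index=counts.index,
    )


def build_signature(de: pd.DataFrame, alpha: float = 0.05) -> Signature:
    """Signed gene set of significant leptin-regulated genes (FDR < alpha)."""
    sig = de[(de["fdr"] < alpha) & np.isfinite(de["fdr"])]
    if sig.empty:
        raise ValueError(
            f"no genes at FDR < {alpha}; consider raising alpha"
        )
    genes = list(sig.index)
    signs = np.sign(sig["log2fc"].to_numpy()).astype(int)
    signs[signs == 0] = 1
    return Signature(genes=genes, signs=signs, alpha=alpha)


@dataclass
class AssociationScore:
    """Per-cell and per-population leptin-association scores.

    ``per_cell`` is the sign-aligned PC1 coordinate; ``per_cell_abs`` is
    its magnitude.  Population aggregates are means over member cells.
    """

    per_cell: np.ndarray
    per_cell_abs: np.ndarray
    per_population: pd.DataFrame
    loadings: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def score_signature(
    scaled: np.ndarray,
    gene_ids: list[str],
    signature: Signature,
    populations: np.ndarray | None = None,
    seed: int = 0,
) -> AssociationScore:
    """Project scaled expression of signature genes onto PC1.

    PC1 is computed over cells on the signature-gene submatrix and its
    sign is aligned so that the sum of loading x signature sign is
    positive; the score therefore rises with leptin-like regulation.
    Invariant to signature gene order and to non-signature genes.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [(g, s) for g, s in zip(signature.genes, signature.signs) if g in index]
    present.sort()  # gene-order invariance
    if len(present) < 2:
        raise ValueError("need >= 2 signature genes present in the matrix")
    cols = [index[g] for g, _ in present]
    signs = np.array([s for _, s in present], dtype=float)
    sub = np.asarray(scaled, dtype=float)[:, cols]
    if np.allclose(sub.var(axis=0), 0):
        raise ValueError("all signature genes have zero variance")

    pca = PCA(n_components=1, random_state=seed)
    pc1 = pca.fit_transform(sub - sub.mean(axis=0, keepdims=True)).ravel()
    loading = pca.components_[0]
    if float(loading @ signs) < 0:
        pc1, loading = -pc1, -loading

    per_pop = pd.DataFrame()
    if populations is not None:
        populations = np.asarray(populations)
        per_pop = (
            pd.DataFrame(
                {"population": populations, "score": pc1, "score_abs": np.abs(pc1)}
            )
            .groupby("population")
            .mean()
            .reset_index()
        )
    return AssociationScore(
        per_cell=pc1,
        per_cell_abs=np.abs(pc1),
        per_population=per_pop,
        loadings=pd.Series(loading, index=[g for g, _ in present]),
    )
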