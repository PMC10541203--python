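"""Normalization, variable-gene selection, scaling and PC embedding.

Normalization defaults to a single-pass pooled size-factor deconvolution:
cells are pooled along a random ring ordering, each pool's summed profile
is compared with the average cell profile to estimate the pool's total
size factor, and per-cell factors are recovered by least squares (anchored
softly to library-size factors to fix the scale).  A plain library-size
mode is available as a fallback.  Expression is then log1p of
factor-divided counts.

Variable genes are ranked by standardized variance: a quadratic
mean-variance trend is fit on log scale, per-value z-scores against the
trend are clipped at sqrt(n_cells), and genes are ranked by the variance
of the clipped z-scores.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr
from sklearn.decomposition import PCA

from .containers import CountMatrix, Embedding, NormalizedMatrix

__all__ = ["normalize", "select_variable_genes", "scale_center", "pca_elbow"]

logger = logging.getLogger(__name__)


def _pooled_size_factors(
    values: sp.csr_matrix, pool_size: int = 20, seed: int = 0
) -> np.ndarray:
    """One-round ring-pool deconvolution of per-cell size factors."""
    n = values.shape[0]
    totals = np.asarray(values.sum(axis=1)).ravel().astype(float)
    lib = totals / totals.mean()
    # average library-normalized profile as the reference
    ref = np.asarray(
        values.multiply((1.0 / lib)[:, None]).mean(axis=0)
    ).ravel()
    expressed = ref > 0

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    w = min(pool_size, n)
    ring = np.concatenate([order, order[: w - 1]])

    rows, cols, data, theta = [], [], [], []
    dense = np.asarray(values.todense(), dtype=float)
    for k in range(n):
        pool = ring[k : k + w]
        pooled = dense[pool].sum(axis=0)
        theta.append(np.median(pooled[expressed] / ref[expressed]))
        rows.extend([k] * w)
        cols.extend(pool.tolist())
        data.extend([1.0] * w)
    # soft library-size anchors fix the scale and the degenerate tiny-n case
    anchor_w = 0.1
    for i in range(n):
        rows.append(n + i)
        cols.append(i)
        data.append(anchor_w)
        theta.append(anchor_w * lib[i])
    A = sp.csr_matrix((data, (rows, cols)), shape=(2 * n, n))
    f = lsqr(A, np.asarray(theta))[0]
    f = np.clip(f, 1e-8, None)
    return f / f.mean()


def normalize(
    counts: CountMatrix, method: str = "pooled", seed: int = 0
) -> NormalizedMatrix:
    """Compute size factors and log-normalize counts.

    ``method`` is "pooled" (default, deconvolved pool factors) or
    "library" (per-cell totals).  A cell with zero total counts is an
    error: such cells should have been removed by QC.
    """
    totals = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts; run QC filtering first")
    if method == "library":
        factors = totals / totals.mean()
    elif method == "pooled":
        factors = _pooled_size_factors(counts.values, seed=seed)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    norm = counts.values.multiply((1.0 / factors)[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    return NormalizedMatrix(norm, factors, list(counts.barcodes), list(counts.gene_ids))


def select_variable_genes(norm: NormalizedMatrix, n_top: int = 2000) -> list[str]:
    """Return the ``n_top`` gene ids with highest standardized variance.

    Ties are broken by lexicographic gene id so the selection is
    deterministic.
    """
    if n_top > norm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {norm.n_genes} genes")
    x = np.asarray(norm.values.todense(), dtype=float)
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)

    fit_mask = (mean > 0) & (var > 0)
    expected = np.full_like(var, var[fit_mask].mean() if fit_mask.any() else 1.0)
    if fit_mask.sum() >= 3:
        lm = np.log10(mean[fit_mask])
        lv = np.log10(var[fit_mask])
        coef = np.polyfit(lm, lv, deg=2)
        with np.errstate(divide="ignore"):
            pred = np.polyval(coef, np.log10(np.where(mean > 0, mean, np.nan)))
        expected = np.where(np.isfinite(pred), 10.0**pred, expected)
    expected = np.clip(expected, 1e-12, None)

    clip = np.sqrt(n)
    z = np.clip((x - mean) / np.sqrt(expected), -clip, clip)
    std_var = z.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    std_var = np.where(var > 0, std_var, 0.0)

    order = sorted(range(norm.n_genes), key=lambda i: (-std_var[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n_top]]


def scale_center(
    norm: NormalizedMatrix, genes: list[str], clip: float = 10.0
) -> np.ndarray:
    """Per-gene center to mean 0 / unit variance, clipped to +-clip.

    Zero-variance genes are left at 0 and logged.  Returns a dense
    cells x len(genes) array in the order of ``genes``.
    """
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    cols = [index[g] for g in genes]
    x = np.asarray(norm.values[:, cols].todense(), dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance genes left at 0 during scaling", zero.sum())
    sd_safe = np.where(zero, 1.0, sd)
    scaled = (x - mean) / sd_safe
    scaled[:, zero] = 0.0
    return np.clip(scaled, -clip, clip)


def pca_elbow(
    scaled: np.ndarray,
    pc_min: int = 15,
    pc_max: int = 30,
    elbow_tol: float = 1e-3,
    seed: int = 0,
    barcodes: list[str] | None = None,
) -> Embedding:
    """PCA with automatic scree-elbow retention of 15-30 components.

    Computes ``pc_max + 1`` components and retains the smallest k in
    [pc_min, pc_max] at which the scree curve has flattened: the relative
    drop (vf[k] - vf[k+1]) / vf[k] falls below ``elbow_tol`` (a vanished
    vf[k+1] also counts as flat).  If the curve never flattens, pc_max is
    retained.  Component signs are oriented so the largest-magnitude
    loading of each PC is positive.
    """
    scaled = np.asarray(scaled, dtype=float)
    n_cells, n_genes = scaled.shape
    if n_cells <= pc_max:
        raise ValueError(f"need more than {pc_max} cells, got {n_cells}")
    n_comp = min(pc_max + 1, n_cells - 1, n_genes)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(scaled)

    # orient: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_comp), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]

    vf = pca.explained_variance_ratio_
    hi = min(pc_max, n_comp - 1)
    n_pcs = hi
    for k in range(pc_min, hi + 1):
        if k >= len(vf) - 1:
            break
        drop = vf[k - 1] - vf[k]
        if vf[k] <= 1e-12 or (vf[k - 1] > 0 and drop / vf[k - 1] < elbow_tol):
            n_pcs = k
            break
    return Embedding(
        coordinates=coords[:, :n_pcs],
        variance_fraction=vf[:n_pcs],
        n_pcs=n_pcs,
        barcodes=barcodes or [],
    )
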