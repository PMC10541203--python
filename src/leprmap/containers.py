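"""Core in-memory containers shared across the pipeline.

The pipeline moves cells-by-genes sparse count matrices through QC,
normalization, embedding and clustering.  Each stage consumes and returns
one of the small dataclasses below; all of them validate their own
invariants on construction so downstream code can assume consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "Embedding",
    "ClusterSolution",
]


class ConfigurationError(ValueError):
    """A parameter object violates its documented invariants."""


class FormatError(ValueError):
    """An on-disk input violates the expected file format."""


class EmptyResultError(RuntimeError):
    """A filtering step removed every cell (or gene)."""


@dataclass
class CountMatrix:
    """Sparse cells x genes integer count matrix with identifiers.

    Rows are cell barcodes, columns are gene ids; ``species`` tags the
    dataset of origin so multi-species analyses can track batch membership.
    """

    values: sp.csr_matrix
    barcodes: list[str]
    gene_ids: list[str]
    species: str = "mouse"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = [str(b) for b in self.barcodes]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.barcodes):
            raise FormatError(
                f"matrix has {n_cells} rows but {len(self.barcodes)} barcodes"
            )
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return CountMatrix(
            self.values[idx],
            [self.barcodes[i] for i in idx],
            list(self.gene_ids),
            self.species,
        )

    def subset_genes(self, mask_or_idx, rename: list[str] | None = None) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        gene_ids = rename if rename is not None else [self.gene_ids[i] for i in idx]
        return CountMatrix(
            self.values[:, idx], list(self.barcodes), gene_ids, self.species
        )


def _as_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ValueError(f"boolean mask of length {arr.shape} for axis of {n}")
        return np.flatnonzero(arr)
    return arr.astype(int)


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression (cells x genes) with its size factors.

    ``values`` holds log1p(count / size_factor); size factors are positive
    with mean ~ 1 so normalized library depth is comparable across cells.
    """

    values: sp.csr_matrix
    size_factors: np.ndarray
    barcodes: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if not np.all(np.isfinite(self.size_factors)):
            raise ValueError("non-finite size factors")
        if np.any(self.size_factors <= 0):
            raise ValueError("non-positive size factors")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Cells x retained-PC coordinates plus per-PC explained-variance fractions."""

    coordinates: np.ndarray
    variance_fraction: np.ndarray
    n_pcs: int
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.coordinates.shape[1] != self.n_pcs:
            raise ValueError("coordinate width does not match n_pcs")
        diffs = np.diff(self.variance_fraction[: self.n_pcs])
        if diffs.size and diffs.max() > 1e-12:
            raise ValueError("variance fractions must be nonincreasing")


@dataclass
class ClusterSolution:
    """A partition of cells at one resolution with its mean silhouette."""

    labels: np.ndarray
    resolution: float
    mean_silhouette: float
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.n_clusters != len(np.unique(self.labels)):
            raise ValueError("n_clusters does not match labels")
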