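"""Reading and writing 10x-style Matrix Market count directories.

A count directory holds ``matrix.mtx``, ``barcodes.tsv`` and
``features.tsv`` (each optionally gzipped).  On disk the matrix follows
the 10x convention (genes x cells); in memory it is always cells x genes.
Orientation is resolved by matching the matrix shape against the id
lists, so either on-disk orientation is accepted.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, FormatError

__all__ = ["read_counts_10x", "write_counts_10x"]


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        path = directory / name
        if path.exists():
            return path
    raise FileNotFoundError(f"missing {stem}(.gz) in {directory}")


def _open(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_ids(path: Path, column: int = 0) -> list[str]:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    return df.iloc[:, column].tolist()


def read_counts_10x(directory, species: str = "mouse") -> CountMatrix:
    """Read a 10x-style MTX triplet directory as a cells x genes matrix."""
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    barcodes = _read_ids(_find(directory, "barcodes.tsv"))
    features = _read_ids(_find(directory, "features.tsv"))
    if len(set(features)) != len(features):
        raise FormatError(f"duplicate gene ids in {directory / 'features.tsv'}")
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcodes in {directory / 'barcodes.tsv'}")

    with _open(mtx_path) as fh:
        values = sp.csr_matrix(scipy.io.mmread(fh))
    n_cells, n_genes = len(barcodes), len(features)
    if values.shape == (n_genes, n_cells) and n_genes != n_cells:
        values = values.T.tocsr()
    elif values.shape == (n_cells, n_genes):
        pass  # already cells x genes
    elif values.shape == (n_genes, n_cells):  # square: assume 10x orientation
        values = values.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {values.shape} matches neither "
            f"(genes={n_genes}, cells={n_cells}) orientation"
        )
    return CountMatrix(values, barcodes, features, species)


def write_counts_10x(counts: CountMatrix, directory) -> None:
    """Write the 10x triplet (matrix genes x cells, barcodes, features)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.values.T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(counts.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    features = pd.DataFrame(
        {
            "id": counts.gene_ids,
            "name": counts.gene_ids,
            "type": "Gene Expression",
        }
    )
    features.to_csv(directory / "features.tsv", sep="\t", index=False, header=False)


def write_truth(truth, barcodes: list[str], path) -> None:
    truth.to_frame(barcodes).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source_id", "reference_id"]:
        df.columns = ["source_id", "reference_id"] + list(df.columns[2:])
    return df
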