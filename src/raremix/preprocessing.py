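"""Raw-count preprocessing: gene filtering, log transform, HVG selection, PCA.

The fitting pipeline operates on a low-dimensional embedding of candidate
cells.  This module reproduces the standard route from a raw genes x cells
count matrix to that embedding:

1. drop genes expressed in fewer than ``min_cells`` cells (default 5),
2. ``log(1 + x)`` transform,
3. keep the ``n_top`` (default 1000) genes of largest variance,
4. project cells onto the leading ``n_components`` (default 50) principal
   components of the centered matrix.

The pipeline deliberately performs **no** per-cell library-size
normalization, doublet removal or batch correction: inputs are assumed to
be raw (or upstream-normalized) non-negative counts, and the four steps
above are the whole contract.  Feeding the pipeline its own output is
rejected, because PC scores contain negative values and every step requires
non-negative input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread
from sklearn.decomposition import PCA

__all__ = [
    "CountMatrix",
    "ReducedMatrix",
    "filter_genes",
    "log_transform",
    "select_hvg",
    "pca_reduce",
    "preprocess",
    "read_counts_csv",
    "read_counts_mtx",
]


@dataclass
class CountMatrix:
    """Dense genes x cells expression matrix with string identifiers.

    Values must be non-negative and identifiers unique; both are validated
    on construction so that downstream steps can rely on them.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        n_genes, n_cells = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(n_genes)]
        if not self.cell_ids:
            self.cell_ids = [f"c{j}" for j in range(n_cells)]
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if np.min(self.values, initial=0.0) < 0:
            raise ValueError("count matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ReducedMatrix:
    """Cells x G principal-component score matrix."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reduced matrix must be 2-D (cells x dims)")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match matrix rows")

    @property
    def G(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.G)]
        return pd.DataFrame(self.values, index=self.cell_ids, columns=cols)


def filter_genes(counts: CountMatrix, min_cells: int = 5) -> CountMatrix:
    """Keep genes with nonzero expression in at least ``min_cells`` cells.

    ``min_cells`` is an inclusive lower bound: a gene seen in exactly
    ``min_cells`` cells is retained ("fewer than" is strict).
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_expressing = np.count_nonzero(counts.values > 0, axis=1)
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError(
            f"all genes removed: none expressed in >= {min_cells} cells"
        )
    return CountMatrix(
        counts.values[keep],
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.cell_ids),
    )


def log_transform(counts: CountMatrix) -> CountMatrix:
    """Elementwise natural ``log(1 + x)`` transform."""
    return CountMatrix(
        np.log1p(counts.values), list(counts.gene_ids), list(counts.cell_ids)
    )


def select_hvg(counts: CountMatrix, n_top: int = 1000) -> CountMatrix:
    """Keep the ``n_top`` genes with largest variance across cells.

    Ties are broken by input gene order (stable sort), so the result is
    deterministic for any input.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > counts.n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds available gene count {counts.n_genes}"
        )
    variances = counts.values.var(axis=1)
    order = np.argsort(-variances, kind="stable")[:n_top]
    order = np.sort(order)  # preserve input gene order in the output
    return CountMatrix(
        counts.values[order],
        [counts.gene_ids[j] for j in order],
        list(counts.cell_ids),
    )


def pca_reduce(counts: CountMatrix, n_components: int = 50) -> ReducedMatrix:
    """Project cells onto leading principal components of the centered data.

    Genes are centered but not scaled.  The sign of each component is fixed
    by making its loading of largest absolute value positive, which removes
    the arbitrary sign freedom of the SVD.
    """
    X = counts.values.T  # cells x genes
    if n_components < 1 or n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} must lie in [1, {min(X.shape)}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign convention
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return ReducedMatrix(scores, list(counts.cell_ids))


def preprocess(
    counts: CountMatrix,
    min_cells: int = 5,
    n_top: int = 1000,
    n_components: int = 50,
) -> ReducedMatrix:
    """Full pipeline: filter -> log1p -> HVG -> PCA (fixed order)."""
    filtered = filter_genes(counts, min_cells=min_cells)
    logged = log_transform(filtered)
    n_top = min(n_top, logged.n_genes)
    hvg = select_hvg(logged, n_top=n_top)
    n_components = min(n_components, hvg.n_genes, hvg.n_cells)
    return pca_reduce(hvg, n_components=n_components)


def read_counts_csv(path) -> CountMatrix:
    """Read a dense genes x cells CSV (first column gene IDs, header cell IDs)."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.to_numpy(dtype=float), [str(g) for g in df.index],
                       [str(c) for c in df.columns])


def read_counts_mtx(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read CellRanger-style MTX (genes x cells) with genes.tsv / barcodes.tsv.

    ``genes.tsv`` may have one or two columns (ID, symbol); the first column
    is used as the gene identifier.
    """
    mat = mmread(matrix_path)
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    return CountMatrix(values, [str(g) for g in genes.iloc[:, 0]],
                       [str(b) for b in barcodes.iloc[:, 0]])
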