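"""Reading per-source expression matrices and aligning them on shared genes.

Supported inputs are the 10x-style MTX triplet (``matrix.mtx[.gz]`` +
``features.tsv``/``genes.tsv`` + ``barcodes.tsv``, optionally gzipped), a
dense delimited table (genes x cells, header row of cell barcodes, first
column of gene ids), and an ``.h5ad`` AnnData container.  Counts are kept
column-compressed sparse internally; gene matching across sources is by
exact identifier string.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneExpressionMatrix",
    "MultiSourceDataset",
    "read_counts",
    "align_sources",
    "write_mtx_triplet",
    "write_dense",
]


@dataclass
class GeneExpressionMatrix:
    """A gene-by-cell expression matrix for one data source.

    Parameters
    ----------
    values
        Sparse or dense matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique ordered identifiers for rows and columns.
    stage
        ``"counts"`` for raw counts (must be non-negative), otherwise a
        normalization tag.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    stage: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if sp.issparse(self.values):
            self.values = self.values.tocsc()
        else:
            self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} identifiers")
        if self.stage == "counts":
            mn = self.values.min() if self.values.size else 0
            if mn < 0:
                raise ValueError("counts-stage matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        """Total counts per cell column."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def drop_zero_cells(self) -> "GeneExpressionMatrix":
        """Return a copy without zero-total cells, logging how many were dropped."""
        totals = self.cell_totals()
        keep = totals > 0
        if keep.all():
            return self
        n_dropped = int((~keep).sum())
        logger.warning("dropping %d zero-count cell(s)", n_dropped)
        return GeneExpressionMatrix(
            self.values[:, keep], self.gene_ids, self.cell_ids[keep], self.stage
        )

    def subset_genes(self, genes: np.ndarray) -> "GeneExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if (idx < 0).any():
            missing = np.asarray(genes)[idx < 0][:3]
            raise KeyError(f"genes not present: {list(missing)} ...")
        return GeneExpressionMatrix(
            self.values[idx, :], np.asarray(genes, dtype=object), self.cell_ids, self.stage
        )


@dataclass
class MultiSourceDataset:
    """K gene-by-cell matrices aligned on shared genes, one per data source."""

    matrices: list[GeneExpressionMatrix]
    source_names: list[str]
    shared_genes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.source_names):
            raise ValueError("one source name per matrix required")
        if len(set(self.source_names)) != len(self.source_names):
            raise ValueError("duplicate source names")
        if self.shared_genes is None:
            self.shared_genes = self.matrices[0].gene_ids
        self.shared_genes = np.asarray(self.shared_genes, dtype=object)
        for m in self.matrices:
            if not np.array_equal(m.gene_ids, self.shared_genes):
                raise ValueError("matrices are not aligned on shared_genes")
        all_cells = np.concatenate([m.cell_ids for m in self.matrices])
        if len(all_cells) != len(set(all_cells)):
            raise ValueError("cell identifiers are not unique across sources")

    @property
    def n_sources(self) -> int:
        return len(self.matrices)

    @property
    def n_cells(self) -> int:
        return sum(m.n_cells for m in self.matrices)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.concatenate([m.cell_ids for m in self.matrices])

    @property
    def source_labels(self) -> np.ndarray:
        """Per-cell source assignment, concatenated over sources."""
        return np.concatenate(
            [np.repeat(name, m.n_cells) for name, m in zip(self.source_names, self.matrices)]
        ).astype(object)

    def concatenated_counts(self) -> sp.csc_matrix:
        """All sources side by side as one genes x cells sparse matrix."""
        return sp.hstack([sp.csc_matrix(m.values) for m in self.matrices], format="csc")

    def to_anndata(self):
        """Export as an AnnData (cells x genes) with an ``obs['source']`` column."""
        import anndata as ad

        X = self.concatenated_counts().T.tocsr()
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame({"source": self.source_labels}, index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.shared_genes.astype(str)),
        )
        return adata


def _open_maybe_gz(path: str):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path, "rt")


def _find_companion(directory: str, stems: tuple[str, ...]) -> str:
    for stem in stems:
        for ext in ("", ".gz"):
            p = os.path.join(directory, stem + ext)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def _read_mtx_triplet(path: str) -> GeneExpressionMatrix:
    if os.path.isdir(path):
        directory = path
        matrix_path = _find_companion(directory, ("matrix.mtx",))
    else:
        directory = os.path.dirname(os.path.abspath(path))
        matrix_path = path
    features_path = _find_companion(directory, ("features.tsv", "genes.tsv"))
    barcodes_path = _find_companion(directory, ("barcodes.tsv",))

    with _open_maybe_gz(matrix_path) as fh:
        mat = scipy.io.mmread(fh).tocsc()
    feats = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    gene_ids = feats.iloc[:, 0].astype(str).to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].astype(str).to_numpy(dtype=object)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"MTX declares shape {mat.shape} but companions list "
            f"{len(gene_ids)} genes and {len(cell_ids)} barcodes"
        )
    return GeneExpressionMatrix(mat, gene_ids, cell_ids)


def _read_dense(path: str, sep: str | None = None) -> GeneExpressionMatrix:
    if sep is None:
        sep = "\t" if str(path).rstrip(".gz").endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GeneExpressionMatrix(
        sp.csc_matrix(df.to_numpy(dtype=float)),
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
    )


def _read_h5ad(path: str, source_column: str | None = None) -> GeneExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    X = sp.csc_matrix(X.T) if sp.issparse(X) else sp.csc_matrix(np.asarray(X).T)
    return GeneExpressionMatrix(
        X,
        adata.var_names.astype(str).to_numpy(dtype=object),
        adata.obs_names.astype(str).to_numpy(dtype=object),
    )


_READERS = {
    "mtx_triplet": _read_mtx_triplet,
    "mtx": _read_mtx_triplet,
    "dense_delim": _read_dense,
    "csv": _read_dense,
    "tsv": _read_dense,
    "hdf_container": _read_h5ad,
    "h5": _read_h5ad,
    "h5ad": _read_h5ad,
}


def read_counts(path: str, format: str, drop_zero: bool = True) -> GeneExpressionMatrix:
    """Read a counts matrix in one of the supported on-disk formats.

    Parameters
    ----------
    path
        File (or, for the MTX triplet, file or directory) to read.
    format
        One of ``mtx_triplet``/``mtx``, ``dense_delim``/``csv``/``tsv``,
        ``hdf_container``/``h5``/``h5ad``.
    drop_zero
        Drop cells with zero total counts (cosine normalization is undefined
        for them); a warning is logged when any are removed.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    m = reader(path)
    return m.drop_zero_cells() if drop_zero else m


def align_sources(
    matrices: list[GeneExpressionMatrix], labels: list[str]
) -> MultiSourceDataset:
    """Restrict all sources to their shared genes, in a common order.

    The shared gene order follows the first matrix's gene order filtered to
    the intersection, so aligning already-aligned inputs is an identity
    operation (idempotence).
    """
    if len(matrices) < 2:
        raise ValueError("at least 2 sources are required")
    shared = pd.Index(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared = shared[shared.isin(set(m.gene_ids))]
    if len(shared) == 0:
        raise ValueError("no genes shared across all sources")
    shared_genes = shared.to_numpy(dtype=object)
    aligned = [m.subset_genes(shared_genes) for m in matrices]
    return MultiSourceDataset(aligned, list(labels), shared_genes)


def write_mtx_triplet(m: GeneExpressionMatrix, directory: str) -> None:
    """Write a 10x-convention MTX triplet (uncompressed)."""
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"), sp.coo_matrix(m.values), field="integer"
        if m.stage == "counts" and np.allclose(sp.csc_matrix(m.values).data % 1, 0)
        else "real",
    )
    feats = pd.DataFrame({0: m.gene_ids, 1: m.gene_ids, 2: "Gene Expression"})
    feats.to_csv(os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def write_dense(m: GeneExpressionMatrix, path: str, sep: str = ",") -> None:
    dense = m.values.toarray() if sp.issparse(m.values) else m.values
    pd.DataFrame(dense, index=m.gene_ids, columns=m.cell_ids).to_csv(path, sep=sep)
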