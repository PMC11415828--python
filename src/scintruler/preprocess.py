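"""Normalization and embedding front-end.

Two normalization stages are distinguished.  ``lognorm`` (depth-scaled,
log1p) feeds highly-variable-gene selection and the PCA embedding used for
graph clustering.  ``cosine`` (each cell scaled to unit Euclidean norm)
feeds all nearest-neighbor distance computations, so that distances are
insensitive to sequencing depth and bounded by 2 for any cell pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import GeneExpressionMatrix

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "log_normalize",
    "cosine_normalize",
    "select_hvgs",
    "pca_embed",
]


@dataclass
class NormalizedMatrix:
    """Gene-by-cell matrix at a named normalization stage (lognorm/cosine)."""

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    stage: str
    parent: GeneExpressionMatrix | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("lognorm", "cosine"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if sp.issparse(self.values):
            self.values = self.values.tocsc()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)


@dataclass
class Embedding:
    """Cell-by-dimension coordinates used as clustering input."""

    coordinates: np.ndarray
    cell_ids: np.ndarray
    method_tag: str = "pca"

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


def log_normalize(m: GeneExpressionMatrix, scale_total: float = 1e4) -> NormalizedMatrix:
    """Scale every cell to ``scale_total`` total counts, then log1p.

    Requires a counts-stage matrix with strictly positive cell totals
    (zero-total cells should have been dropped at ingest).
    """
    if m.stage != "counts":
        raise ValueError("log_normalize expects a counts-stage matrix")
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = m.cell_totals()
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0][:3]
        raise ValueError(f"zero-total cell(s) present, e.g. {list(bad)}")
    X = sp.csc_matrix(m.values, dtype=float)
    X = X @ sp.diags(scale_total / totals)
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X, m.gene_ids, m.cell_ids, "lognorm", parent=m)


def cosine_normalize(m: NormalizedMatrix) -> NormalizedMatrix:
    """Scale every cell column to unit Euclidean norm.

    Unit-norm cells make the Euclidean distance depth-free and bounded by 2,
    the convention of the mutual-nearest-neighbors batch literature.
    """
    if m.stage != "lognorm":
        raise ValueError("cosine_normalize expects a lognorm-stage matrix")
    if sp.issparse(m.values):
        sq = np.asarray(m.values.multiply(m.values).sum(axis=0)).ravel()
    else:
        sq = (np.asarray(m.values) ** 2).sum(axis=0)
    norms = np.sqrt(sq)
    if (norms == 0).any():
        bad = m.cell_ids[norms == 0][0]
        raise ValueError(f"cell {bad!r} has an all-zero expression column")
    if sp.issparse(m.values):
        X = m.values @ sp.diags(1.0 / norms)
    else:
        X = m.values / norms
    return NormalizedMatrix(X, m.gene_ids, m.cell_ids, "cosine", parent=m.parent)


def select_hvgs(m: NormalizedMatrix, n_top: int) -> np.ndarray:
    """Rank genes by dispersion (variance/mean of lognorm values) and keep the top ``n_top``.

    Deterministic: ties are broken by gene-identifier order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > m.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={m.n_genes}")
    if sp.issparse(m.values):
        mean = np.asarray(m.values.mean(axis=1)).ravel()
        sqmean = np.asarray(m.values.multiply(m.values).mean(axis=1)).ravel()
    else:
        X = np.asarray(m.values)
        mean = X.mean(axis=1)
        sqmean = (X**2).mean(axis=1)
    var = np.maximum(sqmean - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    order = (
        pd.DataFrame({"gene": m.gene_ids.astype(str), "score": dispersion})
        .sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        .index.to_numpy()
    )
    return m.gene_ids[order[:n_top]]


def pca_embed(
    m: NormalizedMatrix, genes: np.ndarray | None, n_dims: int, seed: int = 0
) -> Embedding:
    """Per-gene standardized PCA scores of the cells.

    Deterministic given the input: the randomized solver is run with a fixed
    state and each component's sign is fixed so its largest-magnitude gene
    loading is positive.
    """
    if genes is not None:
        idx = pd.Index(m.gene_ids).get_indexer(genes)
        if (idx < 0).any():
            raise KeyError("requested genes missing from matrix")
    else:
        idx = np.arange(m.n_genes)
    max_rank = min(m.n_cells - 1, len(idx))
    if n_dims > max_rank:
        raise ValueError(f"n_dims={n_dims} exceeds feasible rank {max_rank}")
    X = m.values[idx, :]
    X = (X.toarray() if sp.issparse(X) else np.asarray(X)).T  # cells x genes
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    pca = PCA(n_components=n_dims, svd_solver="randomized", random_state=int(seed))
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    comp = pca.components_
    flip = np.sign(comp[np.arange(n_dims), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return Embedding(scores, m.cell_ids, method_tag=f"pca{n_dims}")
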