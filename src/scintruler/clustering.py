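"""Per-source broad clusters (SNN + Louvain) and randomized fine clusters.

Broad clusters are communities of a shared-nearest-neighbor (SNN) graph
found by Louvain modularity optimization, run independently for each data
source.  Each broad cluster is then subdivided uniformly at random into
fine clusters — 3 parts if it holds more than 200 cells, 2 parts for 50 to
200 cells, otherwise it is left whole.  Fine clusters are the sampling
units for all downstream distance comparisons; the random split guarantees
they are evenly distributed within their broad cluster rather than
reflecting any sub-structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._utils import child_seeds, seeded_stdlib_random
from .preprocess import Embedding

__all__ = ["ClusterAssignment", "broad_clusters", "split_fine_clusters"]

#: prune SNN edges whose neighbor-set Jaccard similarity is below this
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels across all sources.

    ``broad`` labels are integers local to each source; ``fine`` labels are
    globally unique strings ``"<source>|b<broad>|f<part>"`` so a fine
    cluster never spans sources or broad clusters.
    """

    cell_ids: np.ndarray
    source: np.ndarray
    broad: np.ndarray
    fine: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.source) == len(self.broad) == len(self.fine) == n):
            raise ValueError("per-cell arrays must have equal length")

    def fine_ids(self) -> np.ndarray:
        """Unique fine-cluster identifiers in deterministic order."""
        return np.unique(self.fine)

    def cells_in_fine(self, fine_id: str) -> np.ndarray:
        return np.flatnonzero(self.fine == fine_id)


def _snn_graph(coords: np.ndarray, knn_k: int) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph from a kNN search."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    # neighbor sets include the cell itself (Seurat convention)
    rows = np.repeat(np.arange(n), knn_k + 1)
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # counts of shared neighbors
    shared = shared.tocoo()
    k = knn_k + 1
    jacc = shared.data / (2 * k - shared.data)
    keep = (jacc >= SNN_PRUNE) & (shared.row < shared.col)
    return sp.csr_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def broad_clusters(
    emb: Embedding,
    resolution: float = 0.5,
    knn_k: int = 20,
    rng_seed: int = 0,
) -> np.ndarray:
    """Louvain community labels on the SNN graph of an embedding.

    Labels are renumbered by decreasing community size (0 = largest) so the
    numbering is stable across runs with the same seed.
    """
    if resolution < 0:
        raise ValueError("resolution must be non-negative")
    n = emb.coordinates.shape[0]
    if n < knn_k + 1:
        raise ValueError(f"source has {n} cells, fewer than knn_k+1={knn_k + 1}")
    g_sparse = _snn_graph(np.asarray(emb.coordinates, dtype=float), knn_k)
    coo = g_sparse.tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    with seeded_stdlib_random(rng_seed):
        part = g.community_multilevel(weights=coo.data.tolist(), resolution=resolution)
    labels = np.asarray(part.membership)
    # renumber by size, ties by first occurrence
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="mergesort")]
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[x] for x in labels], dtype=int)


def n_fine_parts(size: int, thresholds: tuple[int, int] = (50, 200)) -> int:
    """Fine-cluster count for a broad cluster of ``size`` cells.

    Strictly more than the upper threshold -> 3, within [lower, upper] -> 2,
    below the lower threshold -> 1 (the cluster is left unchanged).
    """
    lo, hi = thresholds
    if size > hi:
        return 3
    if size >= lo:
        return 2
    return 1


def split_fine_clusters(
    broad: np.ndarray,
    source: np.ndarray,
    rng_seed: int,
    thresholds: tuple[int, int] = (50, 200),
) -> np.ndarray:
    """Randomly subdivide every (source, broad cluster) group into fine clusters.

    Assignment is equal-probability multinomial, resampled until every part
    is nonempty, so fine clusters are evenly distributed within the broad
    cluster and carry no structure of their own.
    """
    broad = np.asarray(broad)
    source = np.asarray(source, dtype=object)
    fine = np.empty(len(broad), dtype=object)
    groups = sorted(set(zip(source.tolist(), broad.tolist())), key=str)
    seeds = child_seeds(rng_seed, len(groups))
    for (src, b), seed in zip(groups, seeds):
        members = np.flatnonzero((source == src) & (broad == b))
        parts = n_fine_parts(len(members), thresholds)
        rng = np.random.default_rng(seed)
        if parts == 1:
            assign = np.zeros(len(members), dtype=int)
        else:
            while True:
                assign = rng.integers(0, parts, size=len(members))
                if len(np.unique(assign)) == parts:
                    break
        for m_idx, part in zip(members, assign):
            fine[m_idx] = f"{src}|b{b}|f{part}"
    return fine
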