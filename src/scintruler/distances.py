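"""Sampling cell pools and building nearest-neighbor distance arrays.

For one fine cluster the comparison is: how far are its cells from cells of
the *same* source versus cells of *other* sources?  A fixed number of query
cells (default 20) is drawn from the fine cluster; a within pool (default
500 cells) is drawn from the rest of the same source, and a between pool is
drawn stratified from every other source (default 500 per source).  For
each query cell the k nearest neighbors (default 15) in each pool are
recorded, yielding two distance arrays of length n_query x k (300 with the
defaults) that feed the permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances

from ._utils import child_seeds
from .clustering import ClusterAssignment
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["DistanceArrays", "sample_pools", "euclidean_distances", "knn_distance_arrays"]


@dataclass
class DistanceArrays:
    """Within- and between-source nearest-neighbor distances for one fine cluster."""

    fine_cluster_id: str
    query_cells: np.ndarray
    within_pool: np.ndarray
    between_pool: np.ndarray
    d_within: np.ndarray
    d_between: np.ndarray
    k_nn: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        nq = len(self.query_cells)
        if len(self.d_within) != nq * self.k_nn or len(self.d_between) != nq * self.k_nn:
            raise ValueError("distance arrays must have length n_query * k_nn")
        if (np.asarray(self.d_within) < 0).any() or (np.asarray(self.d_between) < 0).any():
            raise ValueError("distances must be non-negative")


def sample_pools(
    assign: ClusterAssignment,
    fine_id: str,
    n_query: int = 20,
    n_within: int = 500,
    n_between_per_source: int = 500,
    rng_seed: int = 0,
    within_pool: str = "source",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample query cells and comparison pools for one fine cluster.

    Returns global cell-index arrays ``(query, within, between)``.  All
    draws are without replacement and capped at availability.  The within
    pool is the same-source complement of the fine cluster by default;
    ``within_pool="broad"`` restricts it to the same broad cluster.

    Raises
    ------
    ValueError
        If the within pool would be empty (the fine cluster covers its whole
        source) or no other-source cells exist.
    """
    members = assign.cells_in_fine(fine_id)
    if len(members) == 0:
        raise ValueError(f"fine cluster {fine_id!r} is empty")
    src = assign.source[members[0]]
    same_source = np.flatnonzero(assign.source == src)
    if within_pool == "broad":
        b = assign.broad[members[0]]
        candidates = np.flatnonzero((assign.source == src) & (assign.broad == b))
    elif within_pool == "source":
        candidates = same_source
    else:
        raise ValueError("within_pool must be 'source' or 'broad'")
    within_candidates = np.setdiff1d(candidates, members, assume_unique=True)
    if len(within_candidates) == 0:
        raise ValueError(f"no within-pool cells available for {fine_id!r}")

    other_sources = [s for s in np.unique(assign.source) if s != src]
    if not other_sources:
        raise ValueError("no other-source cells: at least 2 sources required")

    seeds = child_seeds(rng_seed, 2 + len(other_sources))
    rng_q = np.random.default_rng(seeds[0])
    query = np.sort(rng_q.choice(members, size=min(n_query, len(members)), replace=False))
    rng_w = np.random.default_rng(seeds[1])
    within = np.sort(
        rng_w.choice(within_candidates, size=min(n_within, len(within_candidates)), replace=False)
    )
    between_parts = []
    for s, seed in zip(other_sources, seeds[2:]):
        pool = np.flatnonzero(assign.source == s)
        rng_b = np.random.default_rng(seed)
        between_parts.append(
            rng_b.choice(pool, size=min(n_between_per_source, len(pool)), replace=False)
        )
    between = np.sort(np.concatenate(between_parts))
    return query, within, between


def euclidean_distances(
    queries: np.ndarray, pool: np.ndarray, m: NormalizedMatrix
) -> np.ndarray:
    """Query-by-pool Euclidean distance matrix on cosine-stage expression.

    ``queries`` and ``pool`` are cell column indices into ``m`` and must be
    disjoint.
    """
    if m.stage != "cosine":
        raise ValueError("distances are computed on cosine-stage data")
    if np.intersect1d(queries, pool).size:
        raise ValueError("queries and pool must be disjoint")
    X = m.values
    Q = (X[:, queries].toarray() if hasattr(X[:, queries], "toarray") else X[:, queries]).T
    P = (X[:, pool].toarray() if hasattr(X[:, pool], "toarray") else X[:, pool]).T
    return pairwise_distances(np.asarray(Q), np.asarray(P), metric="euclidean")


def knn_distance_arrays(
    dist_within: np.ndarray,
    dist_between: np.ndarray,
    k_nn: int = 15,
    fine_cluster_id: str = "",
    query_cells: np.ndarray | None = None,
    within_pool: np.ndarray | None = None,
    between_pool: np.ndarray | None = None,
    rng_seed: int = 0,
) -> DistanceArrays:
    """Collect each query cell's ``k_nn`` smallest distances in both pools.

    If either pool is smaller than ``k_nn``, k is reduced to the smaller
    pool size for *both* arrays (with a warning) so the arrays stay
    comparable.
    """
    dist_within = np.asarray(dist_within, dtype=float)
    dist_between = np.asarray(dist_between, dtype=float)
    if dist_within.shape[0] != dist_between.shape[0]:
        raise ValueError("distance matrices must share the query dimension")
    k = min(k_nn, dist_within.shape[1], dist_between.shape[1])
    if k < k_nn:
        logger.warning(
            "pool smaller than k_nn=%d for %s; using k=%d for both arrays",
            k_nn, fine_cluster_id or "<fine cluster>", k,
        )
    if k < 1:
        raise ValueError("pools must contain at least one cell")
    d_w = np.sort(np.partition(dist_within, k - 1, axis=1)[:, :k], axis=1).ravel()
    d_b = np.sort(np.partition(dist_between, k - 1, axis=1)[:, :k], axis=1).ravel()
    nq = dist_within.shape[0]
    return DistanceArrays(
        fine_cluster_id=fine_cluster_id,
        query_cells=np.arange(nq) if query_cells is None else np.asarray(query_cells),
        within_pool=np.arange(dist_within.shape[1]) if within_pool is None else np.asarray(within_pool),
        between_pool=np.arange(dist_between.shape[1]) if between_pool is None else np.asarray(between_pool),
        d_within=d_w,
        d_between=d_b,
        k_nn=k,
        rng_seed=rng_seed,
    )
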