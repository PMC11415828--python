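"""The relative within-between distance (RWBD), the integration score, and
the derived recommendation.

RWBD = (mean_between - mean_within) / max(mean_between, mean_within) is a
silhouette-like quantity in [-1, 1]: near +1 the fine cluster sits far from
other sources relative to its own, near 0 the sources are interchangeable,
negative values mean other-source cells are actually *closer*.

The study-level score is the proportion of fine clusters that are both
significantly source-separated (permutation p below ``p_cut``, default 0.1)
and positively separated (RWBD > 0).  A score near 1 means the sources are
distinct; near 0 they are well mixed.  The recommendation bands follow the
integration-method selection chart: below 0.2 any batch-correction method
is suitable, between 0.2 and 0.8 prefer methods balancing batch removal and
biological-signal conservation (Harmony/Scanorama class), above 0.8 simply
merge — the differences are biological, not batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterAssignment

__all__ = [
    "FineClusterStat",
    "rwbd",
    "scintruler_score",
    "recommend",
    "flag_shared_cells",
    "RECOMMENDATION_LABELS",
]

RECOMMENDATION_LABELS = ("any-integration", "balanced-integration", "simple-merge")


@dataclass
class FineClusterStat:
    """Per-fine-cluster summary: distance means, RWBD, and permutation p."""

    fine_cluster_id: str
    source: str
    mean_within: float
    mean_between: float
    rwbd: float
    p_value: float
    n_cells: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rwbd <= 1.0:
            raise ValueError("RWBD must lie in [-1, 1]")


def rwbd(mean_between: float, mean_within: float) -> float:
    """Relative within-between distance, antisymmetric and bounded in [-1, 1]."""
    if mean_between < 0 or mean_within < 0:
        raise ValueError("distance means must be non-negative")
    denom = max(mean_between, mean_within)
    if denom == 0:
        warnings.warn("both distance means are 0 (identical data); RWBD set to 0")
        return 0.0
    return (mean_between - mean_within) / denom


def scintruler_score(stats: list[FineClusterStat], p_cut: float = 0.1) -> float:
    """Proportion of fine clusters with p < p_cut and RWBD > 0."""
    if not stats:
        raise ValueError("no fine-cluster statistics provided")
    if not 0.0 < p_cut < 1.0:
        raise ValueError("p_cut must lie in (0, 1)")
    passes = sum(1 for s in stats if s.p_value < p_cut and s.rwbd > 0)
    return passes / len(stats)


def recommend(score: float, bands: tuple[float, float] = (0.2, 0.8)) -> str:
    """Map a score to an integration recommendation label.

    ``[0, bands[0])`` -> "any-integration" (sources share most information;
    CCA-, Harmony- and Scanorama-class methods all suitable);
    ``[bands[0], bands[1]]`` -> "balanced-integration" (partial sharing;
    prefer methods conserving biological variation);
    ``(bands[1], 1]`` -> "simple-merge" (little sharing; integration would
    erase biology).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    lo, hi = bands
    if score < lo:
        return RECOMMENDATION_LABELS[0]
    if score <= hi:
        return RECOMMENDATION_LABELS[1]
    return RECOMMENDATION_LABELS[2]


def flag_shared_cells(
    stats: list[FineClusterStat],
    assign: ClusterAssignment,
    shared_p: float = 0.9,
) -> set:
    """Cells of fine clusters with p > shared_p and RWBD < 0.

    These clusters are *closer* to other sources than to their own — the
    signature of a cell population shared across sources.
    """
    if not 0.0 < shared_p < 1.0:
        raise ValueError("shared_p must lie in (0, 1)")
    flagged: set = set()
    for s in stats:
        if s.p_value > shared_p and s.rwbd < 0:
            idx = assign.cells_in_fine(s.fine_cluster_id)
            flagged.update(assign.cell_ids[idx].tolist())
    return flagged
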