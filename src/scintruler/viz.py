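"""Diagnostic plots: p-value vs RWBD scatter, score bars, embedding overlay.

Every figure writes a sidecar table (CSV next to the image) holding exactly
the plotted values, so any figure can be re-derived without re-running the
pipeline.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_p_vs_rwbd", "plot_score_bars", "plot_embedding_overlay", "embed_2d"]


def _sidecar(out_path: str) -> str:
    root, _ = os.path.splitext(out_path)
    return root + ".csv"


def plot_p_vs_rwbd(result, out_path: str) -> pd.DataFrame:
    """One point per fine cluster: RWBD (x) against permutation p (y).

    Reference lines mark p = p_cut and RWBD = 0; the lower-right region
    (significant, positively separated) is what the score counts.
    """
    table = result.cluster_table
    if len(table) == 0:
        raise ValueError("result contains no fine clusters")
    fig, ax = plt.subplots(figsize=(6, 5))
    for src, sub in table.groupby("source"):
        ax.scatter(sub["rwbd"], sub["p_value"], label=str(src), alpha=0.8)
    ax.axhline(result.params.get("p_cut", 0.1), ls="--", c="grey", lw=1)
    ax.axvline(0.0, ls="--", c="grey", lw=1)
    ax.set_xlabel("relative within-between distance (RWBD)")
    ax.set_ylabel("permutation p-value")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(title="source", fontsize=8)
    ax.set_title(f"score = {result.score:.2f} ({result.recommendation})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    cols = ["fine_cluster_id", "source", "rwbd", "p_value", "passes", "shared_flag"]
    out = table[cols].copy()
    out.to_csv(_sidecar(out_path), index=False)
    return out


def plot_score_bars(
    rep_results: list[tuple[str, float, float]],
    out_path: str,
    error_mult: float = 3.0,
) -> pd.DataFrame:
    """Bar plot of mean scores per scenario with error_mult x SD whiskers."""
    if not rep_results:
        raise ValueError("no scenarios to plot")
    df = pd.DataFrame(rep_results, columns=["label", "mean", "sd"])
    if (df["sd"] < 0).any():
        raise ValueError("negative SD")
    df["whisker"] = error_mult * df["sd"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(df["label"], df["mean"], yerr=df["whisker"], capsize=4, color="#4878b0")
    ax.set_ylabel("SCIntRuler score")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    df.to_csv(_sidecar(out_path), index=False)
    return df


def plot_embedding_overlay(emb, result, out_path: str) -> pd.DataFrame:
    """2-D embedding colored by source; shared-flagged cells solid, others hollow."""
    coords = np.asarray(emb.coordinates)
    if coords.shape[1] < 2:
        raise ValueError("overlay requires a 2-d embedding")
    cell_ids = np.asarray(emb.cell_ids, dtype=object)
    assign = result.assignment
    pos = pd.Index(cell_ids)
    missing = set(assign.cell_ids.tolist()) - set(cell_ids.tolist())
    if missing:
        raise ValueError(f"embedding missing {len(missing)} cells from the result")
    idx = pos.get_indexer(assign.cell_ids)
    xy = coords[idx, :2]
    shared = np.array([c in result.shared_cell_ids for c in assign.cell_ids])
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    for i, src in enumerate(np.unique(assign.source)):
        sel = assign.source == src
        color = cmap(i % 10)
        solid = sel & shared
        hollow = sel & ~shared
        ax.scatter(xy[hollow, 0], xy[hollow, 1], s=8, facecolors="none",
                   edgecolors=[color], linewidths=0.6, label=f"{src}")
        ax.scatter(xy[solid, 0], xy[solid, 1], s=10, color=[color])
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=8, markerscale=2)
    ax.set_title("solid = shared-flagged cells")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    out = pd.DataFrame(
        {
            "cell_id": assign.cell_ids,
            "source": assign.source,
            "fine": assign.fine,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "shared": shared,
        }
    )
    out.to_csv(_sidecar(out_path), index=False)
    return out


def embed_2d(coordinates: np.ndarray, cell_ids, seed: int = 0):
    """Presentation-only 2-D projection (UMAP with fixed seed) of an embedding."""
    from .preprocess import Embedding

    try:
        import umap

        xy = umap.UMAP(n_components=2, random_state=int(seed)).fit_transform(coordinates)
        tag = "umap"
    except ImportError:  # fall back to the first two input dimensions
        xy = np.asarray(coordinates)[:, :2]
        tag = "first2"
    return Embedding(np.asarray(xy), np.asarray(cell_ids, dtype=object), method_tag=tag)
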