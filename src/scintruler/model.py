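"""Model/Results interface for the full integration-guidance analysis.

``SCIntRuler`` holds a multi-source dataset plus the analysis parameters;
``fit(seed)`` runs the four-step pipeline — per-source clustering, pool
sampling and nearest-neighbor distances, permutation testing, and score
summarization — and returns a ``SCIntRulerResults`` carrying the score, the
per-fine-cluster table, the recommendation, and the shared-cell flags.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import metric
from ._utils import child_seeds
from .clustering import ClusterAssignment, broad_clusters, split_fine_clusters
from .distances import euclidean_distances, knn_distance_arrays, sample_pools
from .io import MultiSourceDataset
from .metric import FineClusterStat, flag_shared_cells, recommend, rwbd, scintruler_score
from .permtest import permutation_test
from .preprocess import (
    Embedding,
    cosine_normalize,
    log_normalize,
    pca_embed,
    select_hvgs,
)

__all__ = ["SCIntRuler", "SCIntRulerResults", "RepeatResult", "run_study", "repeat_study"]


@dataclass
class SCIntRulerResults:
    """Fitted results: score, per-cluster table, recommendation, shared cells.

    ``cluster_table`` has one row per fine cluster with columns
    ``fine_cluster_id, source, n_cells, mean_within, mean_between, rwbd,
    p_value, passes, shared_flag``.  ``skipped`` lists fine clusters for
    which no test could be computed; they are excluded from the score
    denominator.
    """

    score: float
    recommendation: str
    cluster_table: pd.DataFrame
    shared_cell_ids: set
    assignment: ClusterAssignment
    params: dict
    seed: int
    skipped: list = field(default_factory=list)

    @property
    def stats(self) -> list[FineClusterStat]:
        return [
            FineClusterStat(
                fine_cluster_id=r.fine_cluster_id,
                source=r.source,
                mean_within=r.mean_within,
                mean_between=r.mean_between,
                rwbd=r.rwbd,
                p_value=r.p_value,
                n_cells=int(r.n_cells),
            )
            for r in self.cluster_table.itertuples(index=False)
        ]

    def summary(self) -> str:
        """Plain-text summary in the style of statistical modelling packages."""
        t = self.cluster_table
        lines = [
            "SCIntRuler integration-guidance results",
            "=" * 55,
            f"Sources:                 {t['source'].nunique()}",
            f"Fine clusters tested:    {len(t)}" + (f" (+{len(self.skipped)} skipped)" if self.skipped else ""),
            f"Passing (p<{self.params['p_cut']}, RWBD>0): {int(t['passes'].sum())}",
            f"Shared-flagged clusters: {int(t['shared_flag'].sum())}",
            f"SCIntRuler score:        {self.score:.3f}",
            f"Recommendation:          {self.recommendation}",
            "-" * 55,
            t.to_string(
                index=False,
                formatters={
                    "mean_within": "{:.4f}".format,
                    "mean_between": "{:.4f}".format,
                    "rwbd": "{:+.3f}".format,
                    "p_value": "{:.4f}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def save(self, directory: str) -> None:
        """Write the cluster table (TSV) and a JSON summary into ``directory``."""
        os.makedirs(directory, exist_ok=True)
        self.cluster_table.to_csv(os.path.join(directory, "cluster_table.tsv"), sep="\t", index=False)
        payload = {
            "score": self.score,
            "recommendation": self.recommendation,
            "n_fine_clusters": int(len(self.cluster_table)),
            "n_skipped": len(self.skipped),
            "n_shared_cells": len(self.shared_cell_ids),
            "seed": self.seed,
            "params": self.params,
        }
        with open(os.path.join(directory, "summary.json"), "w") as fh:
            json.dump(payload, fh, indent=2)

    def plot_p_vs_rwbd(self, out_path: str):
        from .viz import plot_p_vs_rwbd

        return plot_p_vs_rwbd(self, out_path)

    def plot_embedding_overlay(self, emb, out_path: str):
        from .viz import plot_embedding_overlay

        return plot_embedding_overlay(emb, self, out_path)


class SCIntRuler:
    """Integration-guidance model over a multi-source expression dataset.

    Parameters
    ----------
    data
        Aligned multi-source dataset (>= 2 sources).
    n_hvg, n_pcs, resolution, knn_k
        Per-source clustering front-end: number of highly variable genes,
        PCA dimensions, Louvain resolution, and kNN graph size.
    n_query, n_within, n_between_per_source, k_nn
        Fine-cluster sampling scheme: query cells per fine cluster, within
        pool size, between pool size per other source, and nearest
        neighbors kept per query.
    n_perm
        Monte-Carlo permutations per fine cluster.
    p_cut, shared_p
        Score threshold (p < p_cut and RWBD > 0 counts toward the score)
        and shared-cell threshold (p > shared_p and RWBD < 0 flags cells).
    distance_genes
        ``"all"`` computes distances over all shared genes (the default);
        ``"hvg"`` restricts to the union of per-source HVGs.
    within_pool
        ``"source"`` draws the within pool from the whole same-source
        complement of the fine cluster; ``"broad"`` restricts it to the
        same broad cluster.
    """

    def __init__(
        self,
        data: MultiSourceDataset,
        *,
        n_hvg: int = 2000,
        n_pcs: int = 50,
        resolution: float = 0.5,
        knn_k: int = 20,
        fine_thresholds: tuple[int, int] = (50, 200),
        n_query: int = 20,
        n_within: int = 500,
        n_between_per_source: int = 500,
        k_nn: int = 15,
        n_perm: int = 1000,
        p_cut: float = 0.1,
        shared_p: float = 0.9,
        bands: tuple[float, float] = (0.2, 0.8),
        scale_total: float = 1e4,
        distance_genes: str = "all",
        within_pool: str = "source",
        raw_pvalue: bool = False,
    ) -> None:
        if data.n_sources < 2:
            raise ValueError("the metric requires at least 2 data sources")
        if distance_genes not in ("all", "hvg"):
            raise ValueError("distance_genes must be 'all' or 'hvg'")
        self.data = data
        self.params = dict(
            n_hvg=n_hvg,
            n_pcs=n_pcs,
            resolution=resolution,
            knn_k=knn_k,
            fine_thresholds=tuple(fine_thresholds),
            n_query=n_query,
            n_within=n_within,
            n_between_per_source=n_between_per_source,
            k_nn=k_nn,
            n_perm=n_perm,
            p_cut=p_cut,
            shared_p=shared_p,
            bands=tuple(bands),
            scale_total=scale_total,
            distance_genes=distance_genes,
            within_pool=within_pool,
            raw_pvalue=raw_pvalue,
        )

    @classmethod
    def from_anndata(cls, adata, source_key: str = "source", **params) -> "SCIntRuler":
        """Build the model from an AnnData (cells x genes) with a source column."""
        import scipy.sparse as sp

        from .io import GeneExpressionMatrix, align_sources

        if source_key not in adata.obs:
            raise KeyError(f"obs column {source_key!r} not found")
        matrices, labels = [], []
        for src in pd.unique(adata.obs[source_key]):
            sub = adata[adata.obs[source_key] == src]
            X = sub.X.T if sp.issparse(sub.X) else np.asarray(sub.X).T
            matrices.append(
                GeneExpressionMatrix(
                    sp.csc_matrix(X),
                    sub.var_names.to_numpy(dtype=object),
                    sub.obs_names.to_numpy(dtype=object),
                ).drop_zero_cells()
            )
            labels.append(str(src))
        return cls(align_sources(matrices, labels), **params)

    @classmethod
    def from_matrices(cls, matrices, labels, **params) -> "SCIntRuler":
        from .io import align_sources

        return cls(align_sources(list(matrices), list(labels)), **params)

    # ------------------------------------------------------------------ fit

    def _cluster(self, seed: int) -> tuple[ClusterAssignment, dict, set]:
        """Per-source lognorm -> HVG -> PCA -> Louvain -> random fine split."""
        p = self.params
        seeds = child_seeds(seed, 2 * self.data.n_sources + 1)
        broad_all, hvg_union = [], set()
        for k, (m, src) in enumerate(zip(self.data.matrices, self.data.source_names)):
            ln = log_normalize(m, p["scale_total"])
            hvgs = select_hvgs(ln, min(p["n_hvg"], ln.n_genes))
            hvg_union.update(hvgs.tolist())
            n_dims = min(p["n_pcs"], ln.n_cells - 1, len(hvgs))
            emb = pca_embed(ln, hvgs, n_dims)
            labels = broad_clusters(
                emb, resolution=p["resolution"], knn_k=min(p["knn_k"], ln.n_cells - 1),
                rng_seed=seeds[2 * k],
            )
            broad_all.append(labels)
        broad = np.concatenate(broad_all)
        source = self.data.source_labels
        fine = split_fine_clusters(broad, source, seeds[-1], thresholds=p["fine_thresholds"])
        assign = ClusterAssignment(
            cell_ids=self.data.cell_ids, source=source, broad=broad, fine=fine, rng_seed=seed
        )
        return assign, {}, hvg_union

    def _cosine_matrix(self, hvg_union: set):
        """Cosine-stage matrix over all shared genes (or the HVG union)."""
        p = self.params
        mats = [cosine_normalize(log_normalize(m, p["scale_total"])) for m in self.data.matrices]
        import scipy.sparse as sp

        from .preprocess import NormalizedMatrix

        X = sp.hstack([sp.csc_matrix(m.values) for m in mats], format="csc")
        nm = NormalizedMatrix(X, self.data.shared_genes, self.data.cell_ids, "cosine")
        if p["distance_genes"] == "hvg":
            genes = np.asarray(sorted(hvg_union), dtype=object)
            idx = pd.Index(nm.gene_ids).get_indexer(genes)
            nm = cosine_normalize(
                NormalizedMatrix(X[idx, :], genes, self.data.cell_ids, "lognorm")
            )
        # densify once when affordable: repeated slicing dominates otherwise
        if nm.n_genes * nm.n_cells <= 40_000_000:
            nm = NormalizedMatrix(nm.dense(), nm.gene_ids, nm.cell_ids, "cosine")
        return nm

    def fit(self, seed: int = 0) -> SCIntRulerResults:
        """Run the full pipeline; fully reproducible given ``seed``."""
        p = self.params
        for m, src in zip(self.data.matrices, self.data.source_names):
            if m.n_cells < p["k_nn"] + 1:
                raise ValueError(
                    f"source {src!r} has only {m.n_cells} cells; "
                    f"at least k_nn+1={p['k_nn'] + 1} required"
                )
        assign, _, hvg_union = self._cluster(seed)
        cosine = self._cosine_matrix(hvg_union)

        fine_ids = assign.fine_ids()
        seeds = child_seeds(seed + 1, 2 * len(fine_ids))
        rows, skipped = [], []
        for j, fid in enumerate(fine_ids):
            members = assign.cells_in_fine(fid)
            try:
                query, within, between = sample_pools(
                    assign,
                    fid,
                    n_query=p["n_query"],
                    n_within=p["n_within"],
                    n_between_per_source=p["n_between_per_source"],
                    rng_seed=seeds[2 * j],
                    within_pool=p["within_pool"],
                )
                dw = euclidean_distances(query, within, cosine)
                db = euclidean_distances(query, between, cosine)
                arrays = knn_distance_arrays(
                    dw, db, k_nn=p["k_nn"], fine_cluster_id=str(fid),
                    query_cells=query, within_pool=within, between_pool=between,
                )
                perm = permutation_test(
                    arrays.d_within,
                    arrays.d_between,
                    n_perm=p["n_perm"],
                    rng_seed=seeds[2 * j + 1],
                    raw_pvalue=p["raw_pvalue"],
                )
            except ValueError as exc:
                skipped.append((str(fid), str(exc)))
                continue
            mw = float(arrays.d_within.mean())
            mb = float(arrays.d_between.mean())
            rows.append(
                dict(
                    fine_cluster_id=str(fid),
                    source=str(assign.source[members[0]]),
                    n_cells=int(len(members)),
                    mean_within=mw,
                    mean_between=mb,
                    rwbd=rwbd(mb, mw),
                    p_value=perm.p_value,
                    t_obs=perm.t_obs,
                )
            )
        if not rows:
            raise ValueError("no fine cluster produced a computable test")
        table = pd.DataFrame(rows)
        stats = [
            FineClusterStat(
                r["fine_cluster_id"], r["source"], r["mean_within"], r["mean_between"],
                r["rwbd"], r["p_value"], r["n_cells"],
            )
            for r in rows
        ]
        score = scintruler_score(stats, p_cut=p["p_cut"])
        shared = flag_shared_cells(stats, assign, shared_p=p["shared_p"])
        table["passes"] = (table["p_value"] < p["p_cut"]) & (table["rwbd"] > 0)
        table["shared_flag"] = (table["p_value"] > p["shared_p"]) & (table["rwbd"] < 0)
        return SCIntRulerResults(
            score=score,
            recommendation=recommend(score, bands=p["bands"]),
            cluster_table=table,
            shared_cell_ids=shared,
            assignment=assign,
            params=dict(p),
            seed=seed,
            skipped=skipped,
        )


def run_study(data: MultiSourceDataset, config: dict | None = None, seed: int = 0) -> SCIntRulerResults:
    """One-call pipeline: build the model from ``data`` and fit it."""
    return SCIntRuler(data, **(config or {})).fit(seed)


@dataclass
class RepeatResult:
    """Score distribution over Monte-Carlo replicate datasets."""

    scores: np.ndarray
    label: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1))


def repeat_study(
    make_data,
    n_reps: int,
    config: dict | None = None,
    seed: int = 0,
    label: str = "",
) -> RepeatResult:
    """Run the pipeline on ``n_reps`` independently generated datasets.

    ``make_data(rep_seed)`` must return a fresh ``MultiSourceDataset``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2 (SD undefined otherwise)")
    seeds = child_seeds(seed, 2 * n_reps)
    scores = []
    for i in range(n_reps):
        data = make_data(seeds[2 * i])
        res = run_study(data, config=config, seed=seeds[2 * i + 1])
        scores.append(res.score)
    return RepeatResult(scores=np.asarray(scores), label=label)
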