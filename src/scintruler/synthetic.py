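"""Synthetic multi-source scRNA-seq counts with controlled information sharing.

The generator draws negative-binomial counts from a hierarchical model:

    mu[g, cell] = base_mean[g] * 2**(marker_lfc * M[type(cell), g]) * batch[source(cell), g]

where ``base_mean`` is a gamma-distributed per-gene baseline, ``M`` marks a
disjoint block of marker genes per cell type (log2 fold change
``marker_lfc``), and ``batch`` is a per-source log-normal factor with
log-scale standard deviation ``batch_effect_sd``.  Counts are NB with a
common dispersion phi (variance mu + phi * mu^2).

Which cell types appear in which source — the *presence* structure — is
what the study scenarios control, from fully disjoint type sets (no shared
information) to identical composition in every source (fully shared).
Presets default to ``batch_effect_sd = 0``: they emulate study designs in
which the sources are splits of one experiment, so any cross-source
separation is purely biological.  Ground-truth type labels are returned for
validation but never consumed by the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GeneExpressionMatrix, MultiSourceDataset, align_sources

__all__ = ["ScenarioConfig", "generate", "scenario_preset", "PRESET_NAMES"]

PRESET_NAMES = ("disjoint", "low_overlap", "high_overlap", "fully_shared")


@dataclass
class ScenarioConfig:
    """Full description of one synthetic multi-source scenario."""

    n_sources: int = 3
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC")
    #: per source, the tuple of present types
    presence: tuple[tuple[str, ...], ...] = (
        ("typeA", "typeB", "typeC"),
    ) * 3
    #: cells per (present) type in each source
    n_cells_per_type: dict = field(default_factory=lambda: {"typeA": 500, "typeB": 500, "typeC": 500})
    n_genes: int = 2000
    n_marker_genes_per_type: int = 100
    marker_lfc: float = 1.5
    batch_effect_sd: float = 0.0
    nb_dispersion: float = 0.5
    base_mean: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_sources < 1 or len(self.presence) != self.n_sources:
            raise ValueError("presence must list the types of each source")
        for types in self.presence:
            if len(types) == 0:
                raise ValueError("every source must contain at least one cell type")
            for t in types:
                if t not in self.cell_types:
                    raise ValueError(f"unknown cell type {t!r}")
                if self.n_cells_per_type.get(t, 0) <= 0:
                    raise ValueError(f"n_cells_per_type missing/invalid for {t!r}")
        if self.n_marker_genes_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("marker blocks exceed n_genes (markers must be disjoint)")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + phi*mu^2."""
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def generate(cfg: ScenarioConfig) -> tuple[MultiSourceDataset, pd.DataFrame]:
    """Draw one multi-source dataset; bit-reproducible given ``cfg.rng_seed``.

    Returns the aligned dataset and a truth table
    ``(cell_id, source, cell_type)`` for validation only.
    """
    cfg.validate()
    rng = np.random.default_rng(int(cfg.rng_seed))
    G = cfg.n_genes
    gene_ids = np.array([f"gene{i:05d}" for i in range(G)], dtype=object)
    base = rng.gamma(shape=2.0, scale=cfg.base_mean / 2.0, size=G)
    base = np.maximum(base, 1e-4)

    marker_fc = {}
    for t_idx, t in enumerate(cfg.cell_types):
        fc = np.ones(G)
        block = slice(t_idx * cfg.n_marker_genes_per_type, (t_idx + 1) * cfg.n_marker_genes_per_type)
        fc[block] = 2.0**cfg.marker_lfc
        marker_fc[t] = fc

    matrices, labels, truth_rows = [], [], []
    for k in range(cfg.n_sources):
        src = f"source{k + 1}"
        batch = np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=G)) if cfg.batch_effect_sd > 0 else np.ones(G)
        blocks, cell_ids = [], []
        cell_counter = 0
        for t in cfg.presence[k]:
            n = cfg.n_cells_per_type[t]
            mu = (base * marker_fc[t] * batch)[:, None] * np.ones((1, n))
            blocks.append(_nb_sample(rng, mu, cfg.nb_dispersion))
            for _ in range(n):
                cid = f"{src}_cell{cell_counter:05d}"
                cell_ids.append(cid)
                truth_rows.append((cid, src, t))
                cell_counter += 1
        counts = sp.csc_matrix(np.hstack(blocks))
        m = GeneExpressionMatrix(counts, gene_ids, np.array(cell_ids, dtype=object))
        matrices.append(m.drop_zero_cells())
        labels.append(src)

    truth = pd.DataFrame(truth_rows, columns=["cell_id", "source", "cell_type"])
    if cfg.n_sources >= 2:
        data = align_sources(matrices, labels)
    else:
        data = MultiSourceDataset(matrices, labels)
    kept = set(data.cell_ids.tolist())
    truth = truth[truth["cell_id"].isin(kept)].reset_index(drop=True)
    return data, truth


def scenario_preset(name: str, rng_seed: int = 0, **overrides) -> ScenarioConfig:
    """Named study scenarios ordered by increasing cross-source sharing.

    - ``disjoint``: each source holds one private cell type (no sharing).
    - ``low_overlap``: one shared type at low abundance (300 cells) plus two
      private types (600 each) per source.
    - ``high_overlap``: the shared type dominates (1350 cells) with a small
      private type (150) per source.
    - ``fully_shared``: identical three-type composition in every source.

    All presets use 1500 cells per source, 2000 genes, and no batch effect;
    pass ``overrides`` (any ScenarioConfig field) to change that.
    """
    if name == "disjoint":
        cfg = ScenarioConfig(
            cell_types=("typeA", "typeB", "typeC"),
            presence=(("typeA",), ("typeB",), ("typeC",)),
            n_cells_per_type={"typeA": 1500, "typeB": 1500, "typeC": 1500},
        )
    elif name == "low_overlap":
        cfg = ScenarioConfig(
            cell_types=("shared", "p1a", "p1b", "p2a", "p2b", "p3a", "p3b"),
            presence=(
                ("shared", "p1a", "p1b"),
                ("shared", "p2a", "p2b"),
                ("shared", "p3a", "p3b"),
            ),
            n_cells_per_type={
                "shared": 300,
                "p1a": 600, "p1b": 600,
                "p2a": 600, "p2b": 600,
                "p3a": 600, "p3b": 600,
            },
        )
    elif name == "high_overlap":
        cfg = ScenarioConfig(
            cell_types=("shared", "priv1", "priv2", "priv3"),
            presence=(("shared", "priv1"), ("shared", "priv2"), ("shared", "priv3")),
            n_cells_per_type={"shared": 1350, "priv1": 150, "priv2": 150, "priv3": 150},
        )
    elif name == "fully_shared":
        cfg = ScenarioConfig()  # three shared types, identical everywhere
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return replace(cfg, rng_seed=rng_seed, **overrides)
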