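import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from scintruler.io import GeneExpressionMatrix
from scintruler.synthetic import ScenarioConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: reduced pipeline parameters for fast full-pipeline tests
SMALL_PIPELINE = dict(
    n_hvg=300,
    n_pcs=20,
    knn_k=15,
    n_query=10,
    n_within=150,
    n_between_per_source=150,
    k_nn=10,
    n_perm=200,
)


def counts_matrix(values, gene_ids=None, cell_ids=None):
    """Build a GeneExpressionMatrix from a dense array of counts."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(c)]
    return GeneExpressionMatrix(sp.csc_matrix(values), gene_ids, cell_ids)


@pytest.fixture
def two_type_config():
    """Small two-type, two-source scenario with clear markers."""
    return ScenarioConfig(
        n_sources=2,
        cell_types=("alpha", "beta"),
        presence=(("alpha", "beta"), ("alpha", "beta")),
        n_cells_per_type={"alpha": 120, "beta": 120},
        n_genes=400,
        n_marker_genes_per_type=60,
        marker_lfc=3.0,
        base_mean=1.0,
        rng_seed=11,
    )


@pytest.fixture
def small_shared_data():
    """Three exchangeable sources from one homogeneous population."""
    cfg = ScenarioConfig(
        n_sources=3,
        cell_types=("only",),
        presence=(("only",),) * 3,
        n_cells_per_type={"only": 250},
        n_genes=400,
        n_marker_genes_per_type=50,
        batch_effect_sd=0.0,
        rng_seed=5,
    )
    data, truth = generate(cfg)
    return data


@pytest.fixture
def small_disjoint_data():
    """Three sources with mutually exclusive cell types."""
    cfg = ScenarioConfig(
        n_sources=3,
        cell_types=("tA", "tB", "tC"),
        presence=(("tA",), ("tB",), ("tC",)),
        n_cells_per_type={"tA": 250, "tB": 250, "tC": 250},
        n_genes=400,
        n_marker_genes_per_type=60,
        rng_seed=6,
    )
    data, truth = generate(cfg)
    return data
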