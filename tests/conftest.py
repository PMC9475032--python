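import numpy as np
import pandas as pd
import pytest

from scmalig import qc_norm, syndata
from scmalig.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """2 patients x 100 cells, 500 genes, planted CNVs; shared across tests."""
    cfg = syndata.CohortConfig(
        n_patients=2,
        n_cells_per_patient=100,
        n_genes=500,
        n_chromosomes=5,
        malignant_fraction=0.3,
        cnv_events=[("P1", "chr1", 2.0), ("P2", "chr2", 1.5)],
        seed=7,
    )
    counts, positions, truth = syndata.generate_cohort(cfg)
    return cfg, counts, positions, truth


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    _, counts, _, _ = small_cohort
    return qc_norm.normalize_log(counts)


def make_expr(values, gene_ids=None, cell_ids=None, **kwargs) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, **kwargs)


@pytest.fixture
def random_expr():
    rng = np.random.default_rng(42)
    values = rng.gamma(1.0, 1.0, size=(50, 10))
    return make_expr(values)
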