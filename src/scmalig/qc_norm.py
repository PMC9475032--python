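"""Reading count fixtures, QC filtering, log normalization and clustering.

QC uses strict inequalities: a cell is retained when it has *more than*
``min_genes`` detected genes, *more than* ``min_transcripts`` UMIs, and a
mitochondrial fraction strictly *below* ``max_mito_fraction``. Presets
``strt`` (1000, 10000, 0.20) and ``tenx`` (500, 1000, 0.50) are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from scmalig.matrix import MITO_PREFIX, CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

MTX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"


@dataclass(frozen=True)
class QcThresholds:
    min_genes: int
    min_transcripts: int
    max_mito_fraction: float

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_transcripts < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


QC_PRESETS = {
    "strt": QcThresholds(min_genes=1000, min_transcripts=10000, max_mito_fraction=0.20),
    "tenx": QcThresholds(min_genes=500, min_transcripts=1000, max_mito_fraction=0.50),
}


def read_counts(directory: str | Path) -> CountMatrix:
    """Read a Matrix Market count fixture with gene/barcode TSV sidecars.

    Expects ``matrix.mtx`` (genes x cells, integer), ``genes.tsv`` (one gene
    id per line) and ``barcodes.tsv`` (tab-separated with a header; first
    column is the cell id, remaining columns become cell metadata).
    """
    directory = Path(directory)
    for name in (MTX_FILE, GENES_FILE, BARCODES_FILE):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing {name} in {directory}")
    mat = scipy.io.mmread(directory / MTX_FILE)
    mat = sp.csr_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValueError("matrix.mtx contains non-integer values")
    genes = (directory / GENES_FILE).read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = pd.read_csv(directory / BARCODES_FILE, sep="\t", index_col=0, dtype=str)
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but genes.tsv lists {len(genes)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} cells"
        )
    return CountMatrix(
        values=mat,
        gene_ids=genes,
        cell_ids=barcodes.index.tolist(),
        cell_meta=barcodes,
    )


def qc_filter(
    counts: CountMatrix,
    thresholds: QcThresholds,
    mito_prefix: str = MITO_PREFIX,
) -> CountMatrix:
    """Retain cells passing all three QC predicates (strict inequalities)."""
    mat = counts.values
    detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    total = np.asarray(mat.sum(axis=0)).ravel().astype(np.float64)
    mito = counts.mito_mask(mito_prefix)
    mito_counts = np.asarray(mat[mito, :].sum(axis=0)).ravel().astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 1.0)
    keep = (
        (detected > thresholds.min_genes)
        & (total > thresholds.min_transcripts)
        & (mito_frac < thresholds.max_mito_fraction)
    )
    if not keep.any():
        raise ValueError("QC filter removed all cells")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter removed %d/%d cells", n_removed, counts.n_cells)
    return counts.subset_cells(keep)


def normalize_log(counts: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform.

    ``value(g, c) = log(1 + scale_factor * count(g, c) / total(c))``.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    total = np.asarray(counts.values.sum(axis=0)).ravel().astype(np.float64)
    if np.any(total == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(total == 0)[:5]]
        raise ValueError(f"cells with zero total counts: {bad}")
    dense = counts.dense().astype(np.float64)
    values = np.log1p(scale_factor * dense / total[None, :])
    return ExpressionMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        scale_factor=scale_factor,
        cell_meta=counts.cell_meta,
    )


def cluster_cells(
    expr: ExpressionMatrix,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 20,
) -> pd.Series:
    """Graph-based clustering: kNN on top principal components + Leiden.

    Returns a Series mapping cell id to an integer cluster label. The
    algorithm is deterministic under ``seed``.
    """
    if expr.n_cells < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, "
            f"got {expr.n_cells}"
        )
    x = expr.values.T  # cells x genes
    x = x - x.mean(axis=0, keepdims=True)
    n_comp = min(n_pcs, expr.n_cells - 1, expr.n_genes)
    if np.allclose(x, 0):
        # degenerate geometry: all cells identical
        return pd.Series(0, index=pd.Index(expr.cell_ids, name="cell"), name="cluster")
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i in range(idx.shape[0]):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=expr.n_cells, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return pd.Series(labels, index=pd.Index(expr.cell_ids, name="cell"), name="cluster")
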