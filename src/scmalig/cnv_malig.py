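"""Expression-based copy-number inference and malignant-cell calling.

The inference follows the moving-average recipe: per-gene reference-mean
subtraction in log space, residual capping, a centered moving average along
each chromosome (with a symmetric window that shrinks at chromosome ends),
per-cell median centering, re-centering on the reference cells, and
exponentiation to ratio space (baseline 1).

Malignancy is scored as the mean of squared deviations (MSD) of a cell's
CNV profile from the copy-neutral baseline; cells above the chosen
percentile of reference/normal scores are "high CNV", and clusters where
high-CNV cells dominate are called malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scmalig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CnvMatrix:
    """Smoothed relative copy number, cells x genome-ordered genes.

    Values are ratios with baseline 1 (1 = copy neutral). ``gene_order``
    lists genes sorted by chromosome then start; ``chromosomes`` gives each
    gene's chromosome in the same order.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_order: list[str]
    chromosomes: np.ndarray
    reference_cells: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_order)):
            raise ValueError("CNV matrix shape does not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValueError("CNV ratios must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_order)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis with shrinking ends.

    At position ``i`` the symmetric half-width is
    ``min((window-1)//2, i, n-1-i)``, so edge positions average over fewer
    genes rather than being dropped.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    half = (window - 1) // 2
    cum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    out = np.empty_like(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[..., i] = (cum[..., i + h + 1] - cum[..., i - h]) / (2 * h + 1)
    return out


def infer_cnv(
    expr: ExpressionMatrix,
    positions: pd.DataFrame,
    reference_cells: list[str],
    window_size: int = 101,
    cap: float = 3.0,
) -> CnvMatrix:
    """Infer smoothed relative copy-number ratios from log expression.

    Parameters
    ----------
    positions
        Table indexed by gene with columns ``chromosome`` and ``start``
        (1-based). Genes absent from ``expr`` are ignored; chromosomes left
        with fewer than ``window_size`` genes are dropped with a warning.
    reference_cells
        Cells assumed copy-neutral (e.g. normal epithelial cells from
        adjacent normal tissue).
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if cap <= 0:
        raise ValueError("cap must be positive")
    if len(reference_cells) == 0:
        raise ValueError("reference cell set is empty")
    cell_pos = pd.Index(expr.cell_ids)
    ref_idx = cell_pos.get_indexer(reference_cells)
    if np.any(ref_idx < 0):
        missing = [c for c, i in zip(reference_cells, ref_idx) if i < 0]
        raise ValueError(f"reference cells not in expression matrix: {missing[:5]}")

    if "gene" in positions.columns:
        positions = positions.set_index("gene")
    shared = pd.Index(expr.gene_ids).intersection(positions.index)
    if len(shared) == 0:
        raise ValueError("no expressed genes have genome positions")
    pos = positions.loc[shared].copy()
    sizes = pos.groupby("chromosome").size()
    small = sizes[sizes < window_size].index.tolist()
    if small:
        logger.warning(
            "dropping chromosomes with < %d genes: %s", window_size, small
        )
        pos = pos[~pos["chromosome"].isin(small)]
    if len(pos) == 0:
        raise ValueError("no chromosome retains enough genes for the window")
    pos = pos.sort_values(["chromosome", "start"], kind="mergesort")
    ordered_genes = pos.index.tolist()
    chroms = pos["chromosome"].to_numpy()

    gene_pos = pd.Index(expr.gene_ids).get_indexer(ordered_genes)
    x = expr.values[gene_pos, :].T  # cells x genes, log space

    ref_mean = x[ref_idx, :].mean(axis=0)
    resid = x - ref_mean[None, :]
    np.clip(resid, -cap, cap, out=resid)

    smoothed = np.empty_like(resid)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        smoothed[:, cols] = moving_average(resid[:, cols], window_size)

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed -= smoothed[ref_idx, :].mean(axis=0)[None, :]

    return CnvMatrix(
        values=np.exp(smoothed),
        cell_ids=list(expr.cell_ids),
        gene_order=ordered_genes,
        chromosomes=chroms,
        reference_cells=list(reference_cells),
    )


def msd_score(cnv: CnvMatrix, baseline: str = "ratio") -> pd.Series:
    """Mean of squares of deviation from the copy-neutral baseline.

    ``baseline='ratio'`` (default) measures ``mean((value - 1)^2)``;
    ``baseline='log'`` measures ``mean(log(value)^2)``.
    """
    if cnv.values.size == 0:
        raise ValueError("empty CNV matrix")
    if baseline == "ratio":
        dev = cnv.values - 1.0
    elif baseline == "log":
        if cnv.values.min() <= 0:
            raise ValueError("log baseline requires strictly positive ratios")
        dev = np.log(cnv.values)
    else:
        raise ValueError("baseline must be 'ratio' or 'log'")
    scores = np.mean(dev**2, axis=1)
    return pd.Series(scores, index=pd.Index(cnv.cell_ids, name="cell"), name="msd")


def malignancy_threshold(normal_scores, percentile: float = 90.0) -> float:
    """Percentile of normal-cell scores by linear interpolation."""
    scores = np.asarray(normal_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no normal scores provided")
    if scores.size < 2:
        raise ValueError("need at least 2 normal scores")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    return float(np.percentile(scores, percentile, method="linear"))


def call_malignant(
    scores: pd.Series,
    threshold: float,
    clusters: pd.Series,
    dominance: float = 0.5,
) -> pd.DataFrame:
    """Threshold scores and propagate cluster-majority malignant calls.

    A cell is ``high_cnv`` when its score strictly exceeds ``threshold``.
    A cluster is malignant when the fraction of its high-CNV cells strictly
    exceeds ``dominance``; all cells inherit their cluster's call.
    """
    clusters = clusters.reindex(scores.index)
    if clusters.isna().any():
        missing = scores.index[clusters.isna()].tolist()
        raise ValueError(f"cells without a cluster label: {missing[:5]}")
    high = scores > threshold
    frac_high = high.groupby(clusters).mean()
    if (clusters.value_counts() == 0).any():
        raise ValueError("cluster with zero cells")
    malignant_clusters = frac_high[frac_high > dominance].index
    final = clusters.isin(malignant_clusters).map(
        {True: "malignant", False: "normal"}
    )
    return pd.DataFrame(
        {
            "msd_score": scores,
            "high_cnv": high,
            "cluster": clusters,
            "final_call": final,
        }
    )
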