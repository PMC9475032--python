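"""Gene-set scoring, differential expression and score-based stratification.

``module_score`` re-implements the control-bin convention: genes are binned
by average expression, each signature gene draws bin-matched control genes,
and the score is the per-cell mean signature expression minus mean control
expression. ``ssgsea_score`` is the rank-weighted ECDF-difference single
sample statistic. ``deg_test`` applies a Wilcoxon rank-sum test after the
min.pct / log-fold-change pre-filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scmalig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")


def _resolve_set(expr: ExpressionMatrix, gene_set: GeneSet | list[str]) -> list[str]:
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSet) else list(gene_set)
    present = [g for g in genes if g in set(expr.gene_ids)]
    dropped = len(genes) - len(present)
    if dropped:
        logger.warning("dropping %d gene-set genes absent from matrix", dropped)
    if not present:
        raise ValueError("gene set has empty intersection with expression matrix")
    return present


def expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of genes by average expression.

    Genes are ranked by average expression (ties broken by original order)
    and split into ``n_bins`` near-equal groups; returns a bin index per
    gene.
    """
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(avg))
    return (ranks * n_bins) // len(avg)


def module_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Control-bin module score per cell.

    For each signature gene, ``n_ctrl`` control genes are sampled with
    replacement from its average-expression bin; the score is
    ``mean(signature expression) - mean(pooled control expression)``.
    Deterministic under ``seed``.
    """
    genes = _resolve_set(expr, gene_set)
    n_bins = min(n_bins, expr.n_genes)
    avg = expr.values.mean(axis=1)
    bins = expression_bins(avg, n_bins)
    gene_pos = pd.Index(expr.gene_ids).get_indexer(genes)

    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    for gp in gene_pos:
        members = bin_members[bins[gp]]
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_rows)

    sig_mean = expr.values[gene_pos, :].mean(axis=0)
    ctrl_mean = expr.values[ctrl, :].mean(axis=0)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "module_score"
    return pd.Series(
        sig_mean - ctrl_mean, index=pd.Index(expr.cell_ids, name="cell"), name=name
    )


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet | list[str],
    alpha: float = 0.25,
) -> pd.Series:
    """Single-sample rank-weighted enrichment score per cell.

    Per cell, genes are ranked by expression (rank N = highest); walking
    down the ranking, the score accumulates the difference between the
    in-set ECDF weighted by ``rank**alpha`` and the unweighted out-of-set
    ECDF. Depends only on within-cell ranks.
    """
    genes = _resolve_set(expr, gene_set)
    in_set = np.isin(np.asarray(expr.gene_ids), genes)
    n = expr.n_genes
    n_in = int(in_set.sum())
    if n_in == n:
        raise ValueError("gene set equals the full gene universe; out-set undefined")

    scores = np.empty(expr.n_cells)
    for c in range(expr.n_cells):
        x = expr.values[:, c]
        ranks = stats.rankdata(x, method="average")  # 1 = lowest
        order = np.argsort(-ranks, kind="stable")
        hits = in_set[order]
        w = np.abs(ranks[order]) ** alpha
        w_in = np.where(hits, w, 0.0)
        denom = w_in.sum()
        cum_in = np.cumsum(w_in) / denom
        cum_out = np.cumsum(~hits) / (n - n_in)
        scores[c] = float(np.sum(cum_in - cum_out))
    name = gene_set.name if isinstance(gene_set, GeneSet) else "ssgsea"
    return pd.Series(scores, index=pd.Index(expr.cell_ids, name="cell"), name=name)


def log_fold_change(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Natural-log fold change of group means on the expm1 scale.

    ``log(mean(expm1(a)) + 1) - log(mean(expm1(b)) + 1)`` per gene, with
    groups along the last axis.
    """
    return np.log(np.expm1(a).mean(axis=-1) + 1) - np.log(np.expm1(b).mean(axis=-1) + 1)


def deg_test(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    min_pct: float = 0.25,
    logfc_threshold: float = float(np.log(2)),
    correction: str = "bonferroni",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression with pre-filtering.

    Genes are tested only if expressed in at least ``min_pct`` of either
    group AND the absolute log fold change is at least ``logfc_threshold``.
    Correction (``bonferroni`` or ``bh``) is applied over tested genes.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    idx = pd.Index(expr.cell_ids)
    ia = idx.get_indexer(group_a)
    ib = idx.get_indexer(group_b)
    if np.any(ia < 0) or np.any(ib < 0):
        raise ValueError("group cells missing from expression matrix")
    a = expr.values[:, ia]
    b = expr.values[:, ib]

    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    lfc = log_fold_change(a, b)
    tested = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (np.abs(lfc) >= logfc_threshold)

    rows = []
    t_idx = np.flatnonzero(tested)
    if len(t_idx):
        res = stats.mannwhitneyu(
            a[t_idx], b[t_idx], alternative="two-sided", method="auto", axis=1
        )
        stat = np.atleast_1d(res.statistic)
        pvals = np.atleast_1d(res.pvalue)
        if correction == "bonferroni":
            adj = np.minimum(pvals * len(t_idx), 1.0)
        else:
            adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        stat = pvals = adj = np.empty(0)
    for k, g in enumerate(t_idx):
        rows.append(
            {
                "gene": expr.gene_ids[g],
                "mean_diff": a[g].mean() - b[g].mean(),
                "log_fc": lfc[g],
                "fold_change": float(np.exp(lfc[g])),
                "pct_a": pct_a[g],
                "pct_b": pct_b[g],
                "u_statistic": stat[k],
                "p_value": pvals[k],
                "adj_p_value": adj[k],
                "direction": "up" if lfc[g] > 0 else "down",
                "significant": adj[k] < alpha,
            }
        )
    cols = [
        "gene", "mean_diff", "log_fc", "fold_change", "pct_a", "pct_b",
        "u_statistic", "p_value", "adj_p_value", "direction", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def stratify_by_score(
    scores: pd.Series,
    rule: str = "median",
    threshold: float | None = None,
) -> pd.Series:
    """Split cells into high/low groups by score.

    ``rule='median'`` (default) assigns ``high`` to cells strictly above the
    median (ties go to ``low``); ``rule='threshold'`` uses a fixed cutoff.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 cells to stratify")
    if rule == "median":
        cut = float(np.median(scores.to_numpy()))
        if np.all(scores.to_numpy() == scores.iloc[0]):
            raise ValueError("all scores equal; no valid median split")
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        cut = threshold
    else:
        raise ValueError("rule must be 'median' or 'threshold'")
    return pd.Series(
        np.where(scores.to_numpy() > cut, "high", "low"),
        index=scores.index,
        name="stratum",
    )
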