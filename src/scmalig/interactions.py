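"""Ligand-receptor edge scoring between cell-type pairs.

Edge weight is the mean-method product: mean ligand expression in the
sender type times mean receptor expression in the receiver type. An edge
counts as detected only when the expressing-cell fraction reaches the
detection threshold on both sides. Specificity normalizes each side's mean
over all cell types, so specificities of one ligand-receptor pair sum to 1
over all (sender, receiver) combinations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scmalig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "sender", "receiver", "ligand", "receptor",
    "weight", "specificity", "detected",
]


def read_lr_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    cols = [c.lower() for c in pairs.columns]
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("ligand-receptor table needs 'ligand' and 'receptor' columns")
    pairs.columns = cols
    return pairs[["ligand", "receptor"]].drop_duplicates()


def extract_edges(
    expr: ExpressionMatrix,
    cell_types: pd.Series,
    lr_pairs: pd.DataFrame,
    detection_threshold: float = 0.2,
) -> pd.DataFrame:
    """Score every (sender, receiver, ligand, receptor) edge.

    ``cell_types`` maps cell id to a type label and must cover all cells.
    Pairs whose ligand or receptor is absent from the matrix are dropped
    with a warning.
    """
    cell_types = cell_types.reindex(expr.cell_ids)
    if cell_types.isna().any():
        raise ValueError("cell_types must label every cell in the matrix")
    types = sorted(cell_types.unique())
    gene_idx = pd.Index(expr.gene_ids)

    keep, dropped = [], []
    for _, row in lr_pairs.iterrows():
        if row["ligand"] in gene_idx and row["receptor"] in gene_idx:
            keep.append((row["ligand"], row["receptor"]))
        else:
            dropped.append((row["ligand"], row["receptor"]))
    if dropped:
        logger.warning("dropping %d pairs with unknown genes", len(dropped))

    genes = sorted({g for pair in keep for g in pair})
    gpos = gene_idx.get_indexer(genes)
    sub = expr.values[gpos, :]  # involved genes x cells
    mean_by_type = {}
    frac_by_type = {}
    for t in types:
        cols = np.flatnonzero((cell_types == t).to_numpy())
        if cols.size == 0:
            raise ValueError(f"cell type {t!r} has zero cells")
        mean_by_type[t] = pd.Series(sub[:, cols].mean(axis=1), index=genes)
        frac_by_type[t] = pd.Series((sub[:, cols] > 0).mean(axis=1), index=genes)

    rows = []
    for ligand, receptor in keep:
        lig_means = np.array([mean_by_type[t][ligand] for t in types])
        rec_means = np.array([mean_by_type[t][receptor] for t in types])
        lig_total = lig_means.sum()
        rec_total = rec_means.sum()
        for si, sender in enumerate(types):
            for ri, receiver in enumerate(types):
                weight = lig_means[si] * rec_means[ri]
                if lig_total > 0 and rec_total > 0:
                    spec = (lig_means[si] / lig_total) * (rec_means[ri] / rec_total)
                else:
                    spec = 0.0
                detected = bool(
                    frac_by_type[sender][ligand] >= detection_threshold
                    and frac_by_type[receiver][receptor] >= detection_threshold
                )
                rows.append((sender, receiver, ligand, receptor, weight, spec, detected))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def diff_edges(edge_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Compare edge weights across two or more ordered conditions.

    Returns one row per edge with per-step log ratios (zeros replaced by a
    pseudo-weight of the smallest nonzero weight times 1e-3) and a
    ``trend`` column: ``up`` if the raw weight strictly increases at every
    step, ``down`` if it strictly decreases, else ``none``.
    """
    if len(edge_tables) < 2:
        raise ValueError("need at least 2 condition edge tables")
    key = ["sender", "receiver", "ligand", "receptor"]
    universe = edge_tables[0][key]
    merged = universe.copy()
    for i, tab in enumerate(edge_tables):
        tab_keys = tab[key]
        if len(tab_keys) != len(universe) or not (
            tab_keys.sort_values(key).reset_index(drop=True)
            .equals(universe.sort_values(key).reset_index(drop=True))
        ):
            raise ValueError("edge tables have mismatched pair universes")
        merged = merged.merge(
            tab[key + ["weight"]].rename(columns={"weight": f"w{i}"}), on=key
        )
    w = merged[[f"w{i}" for i in range(len(edge_tables))]].to_numpy(float)
    nonzero = w[w > 0]
    eps = (nonzero.min() * 1e-3) if nonzero.size else 1e-12
    w_safe = np.where(w > 0, w, eps)
    for i in range(1, len(edge_tables)):
        merged[f"log_ratio_{i}"] = np.log(w_safe[:, i] / w_safe[:, i - 1])
    up = np.all(np.diff(w, axis=1) > 0, axis=1)
    down = np.all(np.diff(w, axis=1) < 0, axis=1)
    merged["trend"] = np.select([up, down], ["up", "down"], default="none")
    return merged
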