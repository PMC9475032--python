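"""Core matrix containers: UMI counts and log-normalized expression.

Both containers are genes x cells, with explicit identifier lists and a
per-cell metadata table. Validation happens at construction so downstream
stages can assume consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

VALID_TISSUES = ("tumor", "normal", "lymph_node")
VALID_PLATFORMS = ("STRT", "TENX")

MITO_PREFIX = "MT-"


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dupes}")
    return ids


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with identifiers and cell metadata.

    Parameters
    ----------
    values
        Sparse or dense non-negative integer matrix, shape
        ``(n_genes, n_cells)``. Stored as CSR.
    gene_ids, cell_ids
        Unique identifier lists matching the matrix dimensions.
    cell_meta
        Table indexed by cell id with at least columns ``patient``,
        ``tissue`` and ``platform``.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self.values.data = self.values.data.astype(np.int64)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids].copy()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def mito_mask(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        return np.array([g.startswith(prefix) for g in self.gene_ids])

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix restricted to a boolean/index cell mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cell_ids = [self.cell_ids[i] for i in keep]
        return CountMatrix(
            values=self.values[:, keep],
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            cell_meta=self.cell_meta.iloc[keep],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class ExpressionMatrix:
    """Log-normalized expression, genes x cells (dense float64).

    ``values[g, c] = log(1 + scale_factor * count[g, c] / total[c])`` so the
    per-cell inverse transform ``sum(expm1(values[:, c]))`` equals
    ``scale_factor``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = 1e4
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("expression shape does not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log-normalized expression must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids].copy()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[:, keep],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            scale_factor=self.scale_factor,
            cell_meta=self.cell_meta.iloc[keep],
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(genes)
        if np.any(pos < 0):
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values[pos, :],
            gene_ids=list(genes),
            cell_ids=list(self.cell_ids),
            scale_factor=self.scale_factor,
            cell_meta=self.cell_meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)
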