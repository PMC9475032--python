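"""Intra-tumor expression programs and cross-patient meta-programs.

Per patient, candidate program signatures come from two sources: the
positive and negative poles of the top principal components of malignant
cell expression, and the top-loading genes of NMF factors. Signatures are
then scored on all malignant cells, their per-cell score profiles are
correlated (Pearson), and hierarchical clustering groups them; clusters
supported by at least two patients become shared meta-programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF, PCA

from scmalig.matrix import ExpressionMatrix
from scmalig.signatures import module_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProgramSignature:
    patient: str
    source: str  # pc_pos | pc_neg | nmf_factor
    component: int
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signature gene list is empty")

    @property
    def label(self) -> str:
        return f"{self.patient}:{self.source}{self.component}"


@dataclass
class MetaProgram:
    name: str
    members: list[ProgramSignature]
    genes: list[str]
    cell_scores: pd.Series | None = field(default=None, repr=False)

    @property
    def patients(self) -> set[str]:
        return {m.patient for m in self.members}

    @property
    def shared(self) -> bool:
        return len(self.patients) >= 2


def pca_pole_signatures(
    expr: ExpressionMatrix,
    patient: str,
    n_components: int = 6,
    n_genes_per_pole: int = 50,
) -> list[ProgramSignature]:
    """Signatures from the positive and negative poles of top PCs.

    ``expr`` should already be restricted to one patient's malignant cells.
    Returns ``2 * n_components`` signatures (or fewer if the data supports
    fewer components).
    """
    if n_components == 0:
        return []
    if expr.n_cells < n_components + 1:
        raise ValueError("need at least n_components+1 cells")
    x = expr.values.T  # cells x genes
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("degenerate expression: zero variance in every gene")
    n_comp = min(n_components, expr.n_cells - 1, expr.n_genes)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(x - x.mean(axis=0, keepdims=True))
    gene_ids = list(expr.gene_ids)
    out = []
    for k in range(n_comp):
        pos, neg = pole_genes(pca.components_[k], gene_ids, n_genes_per_pole)
        out.append(ProgramSignature(patient, "pc_pos", k, pos))
        out.append(ProgramSignature(patient, "pc_neg", k, neg))
    return out


def pole_genes(
    loadings: np.ndarray, gene_ids: list[str], n: int
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Top-n most positive and most negative loading genes of one component.

    Antisymmetric by construction: negating the loadings swaps the poles.
    """
    order = np.argsort(loadings, kind="stable")
    neg = tuple(gene_ids[i] for i in order[:n])
    pos = tuple(gene_ids[i] for i in order[::-1][:n])
    return pos, neg


def nmf_programs(
    expr: ExpressionMatrix,
    patient: str,
    n_factors: int = 4,
    n_genes: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    center: bool = True,
) -> list[ProgramSignature]:
    """Signatures from the top-loading genes of NMF factors.

    NMF (coordinate descent, NNDSVD-ar init) on non-negative log-normalized
    expression of one patient's malignant cells; deterministic under
    ``seed``. With ``center=True`` expression is centered per gene and
    negative values are clipped to zero first, so factors track relative
    (program) variation instead of absolute expression magnitude.
    """
    x = expr.values.T  # cells x genes, non-negative by construction
    if x.min() < 0:
        raise ValueError("NMF requires non-negative input")
    if center:
        x = np.maximum(x - x.mean(axis=0, keepdims=True), 0.0)
    model = NMF(
        n_components=n_factors,
        init="nndsvdar",
        solver="cd",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-4,
    )
    model.fit(x)
    gene_ids = np.asarray(expr.gene_ids)
    out = []
    for k in range(n_factors):
        loadings = model.components_[k]
        top = np.argsort(-loadings, kind="stable")[:n_genes]
        out.append(ProgramSignature(patient, "nmf_factor", k, tuple(gene_ids[top])))
    return out


def nmf_reconstruction_error(expr: ExpressionMatrix, n_factors: int, seed: int = 0) -> float:
    """Relative Frobenius reconstruction error of the NMF fit."""
    x = expr.values.T
    model = NMF(n_components=n_factors, init="nndsvdar", solver="cd",
                max_iter=2000, random_state=seed, tol=1e-10)
    w = model.fit_transform(x)
    return float(np.linalg.norm(x - w @ model.components_) / np.linalg.norm(x))


def score_signatures(
    signatures: list[ProgramSignature],
    expr: ExpressionMatrix,
    seed: int = 0,
) -> pd.DataFrame:
    """Module-score every signature on every cell (signatures x cells)."""
    rows = {}
    for sig in signatures:
        # one shared seed: identical gene lists must score identically
        rows[sig.label] = module_score(expr, list(sig.genes), seed=seed)
    return pd.DataFrame(rows).T


def cluster_signatures(
    signatures: list[ProgramSignature],
    expr: ExpressionMatrix,
    k: int | None = None,
    cut_height: float | None = None,
    linkage_method: str = "average",
    min_support: int = 2,
    seed: int = 0,
) -> tuple[list[MetaProgram], pd.DataFrame]:
    """Cluster signature score profiles into meta-programs.

    Distance is ``1 - Pearson correlation`` of per-cell module-score
    vectors; hierarchical clustering with the given linkage is cut either
    into ``k`` clusters or at ``cut_height``. Clusters whose members span
    at least two patients are flagged shared; consensus genes are those
    appearing in at least ``min_support`` member signatures.

    Returns the meta-program list and the signature correlation matrix.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures to cluster")
    if k is None and cut_height is None:
        raise ValueError("provide k or cut_height")
    scores = score_signatures(signatures, expr, seed=seed)
    corr = np.corrcoef(scores.values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        labels = fcluster(z, t=cut_height, criterion="distance")

    metas = []
    for lab in sorted(set(labels)):
        members = [s for s, l in zip(signatures, labels) if l == lab]
        gene_counts = pd.Series(
            [g for m in members for g in dict.fromkeys(m.genes)]
        ).value_counts()
        support = min_support if len(members) >= min_support else 1
        consensus = gene_counts[gene_counts >= support].index.tolist()
        metas.append(MetaProgram(name=f"MP{lab}", members=members, genes=consensus))
    corr_df = pd.DataFrame(corr, index=scores.index, columns=scores.index)
    return metas, corr_df


def shared_meta_programs(metas: list[MetaProgram]) -> list[MetaProgram]:
    return [m for m in metas if m.shared]


def assign_programs(
    meta_programs: list[MetaProgram],
    expr: ExpressionMatrix,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label each cell with its argmax meta-program module score.

    Ties (including all-zero score vectors) resolve to the earliest program
    in the given order. Returns ``(labels, score matrix cells x programs)``.
    """
    if not meta_programs:
        raise ValueError("no meta-programs to assign")
    cols = {}
    for mp in meta_programs:
        mp.cell_scores = module_score(expr, mp.genes, seed=seed)
        cols[mp.name] = mp.cell_scores
    scores = pd.DataFrame(cols)
    arr = scores.to_numpy()
    winners = np.argmax(arr, axis=1)  # argmax takes the first maximum
    if np.any((arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1):
        logger.info("ties in program assignment resolved by program order")
    labels = pd.Series(
        [meta_programs[w].name for w in winners],
        index=scores.index,
        name="program",
    )
    return labels, scores
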