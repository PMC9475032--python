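"""Ridge-regression drug-response prediction on pseudo-bulk samples.

Malignant and normal epithelial cells are each split at random into a
fixed number of pseudo-bulk groups (per-gene mean of log-normalized
expression). For every drug in a cell-line panel, a ridge model trained on
standardized panel expression predicts each group's AUC (lower AUC = more
sensitive). Candidate drugs must pass three filters: t-test adjusted
p < 0.05 between tumor and normal groups, log2 fold change < -0.1, and
Pearson correlation with the tumor score < -0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge, RidgeCV
from statsmodels.stats.multitest import multipletests

from scmalig.matrix import ExpressionMatrix
from scmalig.signatures import GeneSet, module_score

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(float(a) for a in np.logspace(-2, 4, 13))


@dataclass
class DrugPanel:
    """Cell-line training panel: expression plus drug-response AUC table."""

    line_expression: pd.DataFrame  # genes x lines, log-normalized
    response: pd.DataFrame  # columns drug, line, auc
    source: str = "panel"
    min_lines: int = 20

    def __post_init__(self) -> None:
        required = {"drug", "line", "auc"}
        if not required.issubset(self.response.columns):
            raise ValueError(f"response table needs columns {sorted(required)}")
        unknown = set(self.response["line"]) - set(self.line_expression.columns)
        if unknown:
            raise ValueError(
                f"response lines missing from expression: {sorted(unknown)[:5]}"
            )

    def drugs(self) -> list[str]:
        counts = self.response.groupby("drug").size()
        usable = counts[counts >= self.min_lines].index.tolist()
        skipped = counts[counts < self.min_lines].index.tolist()
        if skipped:
            logger.warning(
                "skipping %d drugs with < %d measured lines", len(skipped), self.min_lines
            )
        return usable


@dataclass
class PseudobulkSet:
    profiles: pd.DataFrame  # genes x groups
    group_class: pd.Series  # group -> tumor | normal
    tumor_score: pd.Series | None = None
    membership: dict[str, list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateCriteria:
    max_adj_p: float = 0.05
    max_log2fc: float = -0.1
    max_correlation: float = -0.5
    correction: str = "bh"  # or bonferroni
    correlation_method: str = "pearson"  # or spearman


def pseudobulk_groups(
    expr: ExpressionMatrix,
    cell_class: pd.Series,
    n_groups_per_class: int = 50,
    seed: int = 0,
) -> PseudobulkSet:
    """Randomly partition each class into near-equal pseudo-bulk groups.

    ``cell_class`` maps cell id to ``malignant`` or ``normal``; every cell
    of each class lands in exactly one group, and group profiles are
    per-gene means of log-normalized expression. Deterministic under
    ``seed``.
    """
    cell_class = cell_class.reindex(expr.cell_ids).dropna()
    rng = np.random.default_rng(seed)
    idx = pd.Index(expr.cell_ids)
    profiles = {}
    classes = {}
    membership = {}
    for cls, label in (("malignant", "tumor"), ("normal", "normal")):
        cells = cell_class.index[cell_class == cls].tolist()
        if len(cells) < n_groups_per_class:
            raise ValueError(
                f"class {cls!r} has {len(cells)} cells < "
                f"{n_groups_per_class} groups"
            )
        order = rng.permutation(len(cells))
        chunks = np.array_split(order, n_groups_per_class)
        for gi, chunk in enumerate(chunks):
            members = [cells[i] for i in chunk]
            cols = idx.get_indexer(members)
            name = f"{label}_{gi:03d}"
            profiles[name] = expr.values[:, cols].mean(axis=1)
            classes[name] = label
            membership[name] = members
    prof = pd.DataFrame(profiles, index=expr.gene_ids)
    return PseudobulkSet(
        profiles=prof,
        group_class=pd.Series(classes, name="class"),
        membership=membership,
    )


def tumor_score(
    pseudobulks: PseudobulkSet,
    malignant_signature: GeneSet | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Module score of the malignant signature on pseudo-bulk profiles."""
    genes = (
        list(malignant_signature.genes)
        if isinstance(malignant_signature, GeneSet)
        else list(malignant_signature)
    )
    if not genes:
        raise ValueError("empty malignant signature")
    expr = ExpressionMatrix(
        values=pseudobulks.profiles.to_numpy(),
        gene_ids=pseudobulks.profiles.index.tolist(),
        cell_ids=pseudobulks.profiles.columns.tolist(),
        scale_factor=1.0,
    )
    score = module_score(expr, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    score.name = "tumor_score"
    pseudobulks.tumor_score = score
    return score


def _standardize(train: np.ndarray):
    """Per-gene mean/sd over training lines; zero-variance genes get sd 1."""
    mu = train.mean(axis=1, keepdims=True)
    sd = train.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return mu, sd


def ridge_fit_predict(
    panel: DrugPanel,
    pseudobulks: PseudobulkSet,
    lambda_rule: float | tuple[float, ...] = DEFAULT_ALPHA_GRID,
    cv_folds: int = 5,
    min_common_genes: int = 50,
) -> pd.DataFrame:
    """Predict per-group AUC for each panel drug. Returns drugs x groups.

    Per drug: restrict to genes shared by panel and pseudobulks,
    standardize each gene over the drug's training lines and apply the same
    transform to the pseudo-bulk profiles, then fit ridge regression
    (intercept unpenalized). ``lambda_rule`` is either a fixed penalty or a
    grid searched by k-fold cross-validation; a penalty of 0 falls back to
    ordinary least squares.
    """
    common = panel.line_expression.index.intersection(pseudobulks.profiles.index)
    if len(common) < min_common_genes:
        raise ValueError(
            f"only {len(common)} genes shared between panel and pseudobulks "
            f"(need >= {min_common_genes})"
        )
    panel_x = panel.line_expression.loc[common]
    bulk_x = pseudobulks.profiles.loc[common].to_numpy()

    preds = {}
    for drug in panel.drugs():
        resp = panel.response[panel.response["drug"] == drug]
        lines = resp["line"].tolist()
        y = resp["auc"].to_numpy(float)
        x = panel_x[lines].to_numpy()
        mu, sd = _standardize(x)
        xt = ((x - mu) / sd).T  # lines x genes
        bt = ((bulk_x - mu) / sd).T  # groups x genes
        if isinstance(lambda_rule, (int, float)):
            if lambda_rule == 0:
                model = LinearRegression()
            else:
                model = Ridge(alpha=float(lambda_rule))
        else:
            model = RidgeCV(alphas=list(lambda_rule), cv=cv_folds)
        model.fit(xt, y)
        preds[drug] = model.predict(bt)
    return pd.DataFrame(preds, index=pseudobulks.profiles.columns).T


def filter_candidates(
    predictions: pd.DataFrame,
    group_class: pd.Series,
    tumor_scores: pd.Series,
    criteria: CandidateCriteria = CandidateCriteria(),
) -> pd.DataFrame:
    """Apply the three-criterion candidate filter to predicted AUCs.

    Per drug: two-sample t-test (tumor vs normal predicted AUC) corrected
    across drugs, ``log2fc = log2(mean tumor AUC / mean normal AUC)``, and
    the correlation of predicted AUC with the tumor score over all groups.
    Drugs with non-positive mean AUC are excluded with a warning.
    """
    groups = predictions.columns
    cls = group_class.reindex(groups)
    if cls.isna().any():
        raise ValueError("every prediction group needs a class label")
    t_mask = (cls == "tumor").to_numpy()
    n_mask = (cls == "normal").to_numpy()
    if t_mask.sum() < 2 or n_mask.sum() < 2:
        raise ValueError("need at least 2 groups per class")
    scores = tumor_scores.reindex(groups).to_numpy(float)

    rows = []
    for drug in predictions.index:
        pred = predictions.loc[drug].to_numpy(float)
        mean_t = pred[t_mask].mean()
        mean_n = pred[n_mask].mean()
        if mean_t <= 0 or mean_n <= 0:
            logger.warning("drug %s has non-positive mean AUC; excluded", drug)
            continue
        tt = stats.ttest_ind(pred[t_mask], pred[n_mask], equal_var=False)
        if pred.std() == 0 or scores.std() == 0:
            corr = 0.0  # correlation undefined for constant inputs
        elif criteria.correlation_method == "pearson":
            corr = stats.pearsonr(pred, scores).statistic
        else:
            corr = stats.spearmanr(pred, scores).statistic
        if np.isnan(corr):
            corr = 0.0
        rows.append(
            {
                "drug": drug,
                "mean_tumor_auc": mean_t,
                "mean_normal_auc": mean_n,
                "log2fc": float(np.log2(mean_t / mean_n)),
                "p_value": float(tt.pvalue) if np.isfinite(tt.pvalue) else 1.0,
                "tumor_score_correlation": float(corr),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["adj_p_value"] = []
        result["candidate"] = []
        return result
    if criteria.correction == "bonferroni":
        result["adj_p_value"] = np.minimum(result["p_value"] * len(result), 1.0)
    else:
        result["adj_p_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["candidate"] = (
        (result["adj_p_value"] < criteria.max_adj_p)
        & (result["log2fc"] < criteria.max_log2fc)
        & (result["tumor_score_correlation"] < criteria.max_correlation)
    )
    return result.set_index("drug")
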