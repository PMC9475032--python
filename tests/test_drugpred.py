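import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scmalig import qc_norm, syndata
from scmalig.drugpred import (
    CandidateCriteria,
    DrugPanel,
    PseudobulkSet,
    filter_candidates,
    pseudobulk_groups,
    ridge_fit_predict,
    tumor_score,
)
from tests.conftest import make_expr


@pytest.fixture(scope="module")
def cohort_expr():
    cfg = syndata.CohortConfig(
        n_patients=1, n_cells_per_patient=300, n_genes=400,
        n_chromosomes=4, malignant_fraction=0.5, seed=19,
    )
    counts, _, truth = syndata.generate_cohort(cfg)
    return qc_norm.normalize_log(counts), truth


class TestPseudobulk:
    def test_fifty_groups_of_two(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.gamma(1, 1, (30, 200)))
        cls = pd.Series(
            ["malignant"] * 100 + ["normal"] * 100, index=expr.cell_ids
        )
        bulks = pseudobulk_groups(expr, cls, 50, seed=1)
        tumor_groups = [g for g in bulks.membership if g.startswith("tumor")]
        assert len(tumor_groups) == 50
        sizes = [len(bulks.membership[g]) for g in tumor_groups]
        assert all(s == 2 for s in sizes)
        union = [c for g in tumor_groups for c in bulks.membership[g]]
        assert sorted(union) == sorted(expr.cell_ids[:100])
        assert len(set(union)) == 100

    def test_single_group_equals_class_mean(self, cohort_expr):
        expr, truth = cohort_expr
        bulks = pseudobulk_groups(expr, truth.cell_class, 1, seed=0)
        mal = (truth.cell_class == "malignant").to_numpy()
        np.testing.assert_allclose(
            bulks.profiles["tumor_000"].to_numpy(),
            expr.values[:, mal].mean(axis=1),
            atol=1e-12,
        )

    def test_group_means_match_brute_force(self, cohort_expr):
        expr, truth = cohort_expr
        bulks = pseudobulk_groups(expr, truth.cell_class, 10, seed=3)
        idx = pd.Index(expr.cell_ids)
        for group, members in bulks.membership.items():
            cols = idx.get_indexer(members)
            brute = np.zeros(expr.n_genes)
            for c in cols:
                brute += expr.values[:, c]
            brute /= len(cols)
            np.testing.assert_allclose(
                bulks.profiles[group].to_numpy(), brute, atol=1e-12
            )

    def test_deterministic(self, cohort_expr):
        expr, truth = cohort_expr
        b1 = pseudobulk_groups(expr, truth.cell_class, 10, seed=5)
        b2 = pseudobulk_groups(expr, truth.cell_class, 10, seed=5)
        pd.testing.assert_frame_equal(b1.profiles, b2.profiles)

    def test_too_few_cells_errors(self, cohort_expr):
        expr, truth = cohort_expr
        with pytest.raises(ValueError, match="groups"):
            pseudobulk_groups(expr, truth.cell_class, 10**4, seed=0)


class TestTumorScore:
    def test_separates_classes(self, cohort_expr):
        expr, truth = cohort_expr
        bulks = pseudobulk_groups(expr, truth.cell_class, 20, seed=0)
        score = tumor_score(bulks, truth.malignant_markers, seed=0)
        t = score[bulks.group_class == "tumor"]
        n = score[bulks.group_class == "normal"]
        # AUC of separation
        auc = (t.to_numpy()[:, None] > n.to_numpy()[None, :]).mean()
        assert auc >= 0.95

    def test_constant_profiles_zero(self):
        profiles = pd.DataFrame(
            np.full((100, 6), 1.7),
            index=[f"g{i}" for i in range(100)],
            columns=[f"grp{j}" for j in range(6)],
        )
        bulks = PseudobulkSet(
            profiles=profiles,
            group_class=pd.Series("tumor", index=profiles.columns),
        )
        score = tumor_score(bulks, [f"g{i}" for i in range(5)], seed=0)
        np.testing.assert_allclose(score.to_numpy(), 0.0, atol=1e-12)

    def test_group_permutation_equivariant(self, cohort_expr):
        expr, truth = cohort_expr
        bulks = pseudobulk_groups(expr, truth.cell_class, 10, seed=0)
        s1 = tumor_score(bulks, truth.malignant_markers, seed=0)
        perm = bulks.profiles.columns[::-1]
        bulks2 = PseudobulkSet(
            profiles=bulks.profiles[perm], group_class=bulks.group_class.loc[perm]
        )
        s2 = tumor_score(bulks2, truth.malignant_markers, seed=0)
        pd.testing.assert_series_equal(s1.loc[perm], s2, check_names=False)

    def test_empty_signature_errors(self, cohort_expr):
        expr, truth = cohort_expr
        bulks = pseudobulk_groups(expr, truth.cell_class, 5, seed=0)
        with pytest.raises(ValueError, match="empty"):
            tumor_score(bulks, [])


def toy_panel_and_bulks(seed=0, n_lines=10, n_genes=3, noise=0.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    lines = [f"L{i}" for i in range(n_lines)]
    x = rng.uniform(0.5, 3.0, size=(n_genes, n_lines))
    beta = rng.normal(size=n_genes)
    y = 5.0 + beta @ x + rng.normal(0, noise, n_lines)
    panel = DrugPanel(
        line_expression=pd.DataFrame(x, index=genes, columns=lines),
        response=pd.DataFrame({"drug": "d1", "line": lines, "auc": y}),
        min_lines=5,
    )
    b = rng.uniform(0.5, 3.0, size=(n_genes, 4))
    bulks = PseudobulkSet(
        profiles=pd.DataFrame(b, index=genes, columns=list("wxyz")),
        group_class=pd.Series(
            ["tumor", "tumor", "normal", "normal"], index=list("wxyz")
        ),
    )
    return panel, bulks, beta


class TestRidge:
    def test_infinite_penalty_predicts_training_mean(self):
        panel, bulks, _ = toy_panel_and_bulks()
        preds = ridge_fit_predict(panel, bulks, lambda_rule=1e12, min_common_genes=1)
        mean_auc = panel.response["auc"].mean()
        np.testing.assert_allclose(preds.loc["d1"], mean_auc, rtol=1e-6)

    def test_zero_penalty_equals_ols(self):
        panel, bulks, _ = toy_panel_and_bulks()
        preds = ridge_fit_predict(panel, bulks, lambda_rule=0, min_common_genes=1)
        # independent OLS oracle on the standardized design
        x = panel.line_expression.to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        xt = ((x - mu) / sd).T
        design = np.column_stack([np.ones(len(xt)), xt])
        coef, *_ = np.linalg.lstsq(design, panel.response["auc"].to_numpy(), rcond=None)
        bt = (bulks.profiles.to_numpy() - mu) / sd
        expected = coef[0] + bt.T @ coef[1:]
        np.testing.assert_allclose(preds.loc["d1"].to_numpy(), expected, atol=1e-8)

    def test_noiseless_planted_heldout_r2(self):
        # ridge trained on 150 lines recovers held-out AUC with R^2 >= 0.99
        drugs = ["d0"]
        # keep genes < training lines so the noiseless fit is identifiable
        panel, truth = syndata.generate_drug_panel(
            200, 100, drugs, planted_sensitive=["d0"], effect_size=-1.0,
            noise_sd=0.0, seed=4, intercept=8.0,
        )
        lines = panel.line_expression.columns
        train_lines, test_lines = list(lines[:150]), list(lines[150:])
        train = DrugPanel(
            line_expression=panel.line_expression[train_lines],
            response=panel.response[panel.response["line"].isin(train_lines)],
        )
        held = PseudobulkSet(
            profiles=panel.line_expression[test_lines],
            group_class=pd.Series("tumor", index=test_lines),
        )
        preds = ridge_fit_predict(train, held, lambda_rule=(0.01, 0.1, 1.0, 10.0))
        true_auc = (
            panel.response[panel.response["line"].isin(test_lines)]
            .set_index("line")["auc"]
            .loc[test_lines]
        )
        resid = preds.loc["d0"].to_numpy() - true_auc.to_numpy()
        r2 = 1 - (resid**2).sum() / ((true_auc - true_auc.mean()) ** 2).sum()
        assert r2 >= 0.99

    def test_gene_and_cell_order_invariant(self):
        panel, bulks, _ = toy_panel_and_bulks(n_genes=5)
        p1 = ridge_fit_predict(panel, bulks, lambda_rule=1.0, min_common_genes=1)
        shuffled_panel = DrugPanel(
            line_expression=panel.line_expression.iloc[::-1, ::-1],
            response=panel.response,
            min_lines=5,
        )
        shuffled_bulks = PseudobulkSet(
            profiles=bulks.profiles.iloc[::-1],
            group_class=bulks.group_class,
        )
        p2 = ridge_fit_predict(
            shuffled_panel, shuffled_bulks, lambda_rule=1.0, min_common_genes=1
        )
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)

    def test_too_few_common_genes_errors(self):
        panel, bulks, _ = toy_panel_and_bulks()
        with pytest.raises(ValueError, match="shared"):
            ridge_fit_predict(panel, bulks, min_common_genes=50)


class TestFilterCandidates:
    def _inputs(self):
        groups = [f"t{i}" for i in range(5)] + [f"n{i}" for i in range(5)]
        cls = pd.Series(["tumor"] * 5 + ["normal"] * 5, index=groups)
        scores = pd.Series(
            np.concatenate([np.linspace(1, 2, 5), np.linspace(-2, -1, 5)]),
            index=groups,
        )
        return groups, cls, scores

    def test_three_criteria_candidate(self):
        groups, cls, scores = self._inputs()
        rng = np.random.default_rng(0)
        hit = np.concatenate([np.full(5, 0.8), np.full(5, 1.0)])
        hit += rng.normal(0, 0.01, 10)
        null = np.full(10, 1.0) + rng.normal(0, 0.01, 10)
        preds = pd.DataFrame([hit, null], index=["hit", "null"], columns=groups)
        out = filter_candidates(preds, cls, scores)
        assert bool(out.loc["hit", "candidate"])
        assert not bool(out.loc["null", "candidate"])
        assert out.loc["hit", "log2fc"] < -0.1
        assert out.loc["hit", "tumor_score_correlation"] < -0.5

    def test_identical_predictions_not_candidate(self):
        groups, cls, scores = self._inputs()
        preds = pd.DataFrame([np.full(10, 2.0)], index=["flat"], columns=groups)
        out = filter_candidates(preds, cls, scores)
        assert out.loc["flat", "log2fc"] == 0.0
        assert not bool(out.loc["flat", "candidate"])

    def test_ttest_and_bh_match_brute_force(self):
        groups, cls, scores = self._inputs()
        rng = np.random.default_rng(8)
        preds = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(6, 10)),
            index=[f"d{i}" for i in range(6)],
            columns=groups,
        )
        out = filter_candidates(preds, cls, scores)
        t_mask = (cls == "tumor").to_numpy()
        raw = []
        for d in out.index:
            p = stats.ttest_ind(
                preds.loc[d].to_numpy()[t_mask],
                preds.loc[d].to_numpy()[~t_mask],
                equal_var=False,
            ).pvalue
            raw.append(p)
        raw = np.array(raw)
        # brute-force BH: p * m / rank, cumulative minimum from the largest
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 1.0
        for k in range(m - 1, -1, -1):
            running = min(running, raw[order[k]] * m / (k + 1))
            adj[order[k]] = running
        np.testing.assert_allclose(out["p_value"].to_numpy(), raw, atol=1e-10)
        np.testing.assert_allclose(out["adj_p_value"].to_numpy(), adj, atol=1e-10)

    def test_nonpositive_auc_excluded(self):
        groups, cls, scores = self._inputs()
        preds = pd.DataFrame(
            [np.full(10, -1.0), np.full(10, 1.0)], index=["bad", "ok"], columns=groups
        )
        out = filter_candidates(preds, cls, scores)
        assert "bad" not in out.index
        assert "ok" in out.index

    def test_bonferroni_option(self):
        groups, cls, scores = self._inputs()
        rng = np.random.default_rng(2)
        preds = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(4, 10)),
            index=[f"d{i}" for i in range(4)],
            columns=groups,
        )
        out = filter_candidates(
            preds, cls, scores, CandidateCriteria(correction="bonferroni")
        )
        np.testing.assert_allclose(
            out["adj_p_value"], np.minimum(out["p_value"] * 4, 1.0), atol=1e-12
        )

    def test_criteria_invariant(self):
        groups, cls, scores = self._inputs()
        rng = np.random.default_rng(5)
        preds = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(8, 10)),
            index=[f"d{i}" for i in range(8)],
            columns=groups,
        )
        out = filter_candidates(preds, cls, scores)
        manual = (
            (out["adj_p_value"] < 0.05)
            & (out["log2fc"] < -0.1)
            & (out["tumor_score_correlation"] < -0.5)
        )
        assert (out["candidate"] == manual).all()
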