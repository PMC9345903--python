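import numpy as np
import pandas as pd
import pytest

from slscreen import drugs as dm
from slscreen.io_formats import ExpressionMatrix


def make_panel(auc_df, expr_df=None, tissues=None):
    ccls = list(auc_df.index)
    if expr_df is None:
        rng = np.random.default_rng(0)
        expr_df = pd.DataFrame(
            rng.uniform(2, 8, (5, len(ccls))),
            index=[f"G{i}" for i in range(5)],
            columns=ccls,
        )
    meta = pd.Series(tissues or ["kidney"] * len(ccls), index=ccls)
    return dm.DrugPanel(ExpressionMatrix(expr_df, "log2tpm"), auc_df, meta)


class TestPrepPanel:
    def test_compound_above_na_threshold_dropped(self):
        ccls = [f"C{i}" for i in range(5)]
        auc = pd.DataFrame(
            {"keep": [1.0, 2, 3, 4, 5], "drop": [1.0, np.nan, np.nan, 4, 5]},
            index=ccls,
        )
        out = dm.prep_panel(make_panel(auc), na_threshold=0.2, knn_k=1)
        assert list(out.auc.columns) == ["keep"]
        assert out.prep_report["compounds_dropped_na"] == ["drop"]

    def test_knn_k1_imputes_nearest_compound_profile(self):
        ccls = [f"C{i}" for i in range(5)]
        auc = pd.DataFrame(
            {
                "a": [0.7, 1.0, 2.0, 3.0, 4.0],
                "b": [np.nan, 1.0, 2.0, 3.0, 4.0],  # nearest profile is "a"
                "c": [9.0, 9.0, 9.0, 9.0, 9.0],
            },
            index=ccls,
        )
        out = dm.prep_panel(make_panel(auc), na_threshold=0.25, knn_k=1)
        assert out.auc.loc["C0", "b"] == pytest.approx(0.7)

    def test_haematopoietic_lines_always_excluded(self):
        ccls = [f"C{i}" for i in range(4)]
        auc = pd.DataFrame({"a": [1.0, 2, 3, 4]}, index=ccls)
        tissues = ["kidney", "haematopoietic_and_lymphoid_tissue", "kidney", "kidney"]
        out = dm.prep_panel(make_panel(auc, tissues=tissues))
        assert "C1" not in out.auc.index
        assert out.prep_report["n_ccl_excluded_lineage"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ccls = [f"C{i}" for i in range(20)]
        auc = pd.DataFrame(
            rng.uniform(1, 5, (20, 6)),
            index=ccls,
            columns=[f"d{i}" for i in range(6)],
        )
        auc.iloc[0, 0] = np.nan
        once = dm.prep_panel(make_panel(auc), knn_k=3)
        twice = dm.prep_panel(once, knn_k=3)
        pd.testing.assert_frame_equal(once.auc, twice.auc)


class TestTrainRidge:
    def linear_panel(self, n=100, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ccls = [f"C{i}" for i in range(n)]
        x = rng.uniform(0, 1, n)
        expr = pd.DataFrame(
            [x, rng.uniform(0, 1, n)], index=["G_hit", "G_noise"], columns=ccls
        )
        auc = pd.DataFrame(
            {"cmp": 2.0 - x + rng.normal(0, noise, n)}, index=ccls
        )
        return make_panel(auc, expr), x

    def test_noiseless_single_gene_recovery(self):
        panel, x = self.linear_panel()
        model = dm.train_ridge(
            panel, "cmp", lambda_grid=(1e-6,), seed=0, genes=["G_hit"]
        )
        pred = model.predict(panel.ccl_expr.values)
        np.testing.assert_allclose(pred.to_numpy(), 2.0 - x, atol=1e-6)

    def test_constant_auc_gives_intercept_only(self):
        panel, _ = self.linear_panel()
        panel.auc["cmp"] = 3.5
        model = dm.train_ridge(panel, "cmp", seed=0)
        assert model.intercept == pytest.approx(3.5)
        np.testing.assert_allclose(model.coef, 0.0, atol=1e-9)

    def test_seed_fixes_cv_split_and_lambda(self):
        panel, _ = self.linear_panel(noise=0.3, seed=5)
        m1 = dm.train_ridge(panel, "cmp", seed=11)
        m2 = dm.train_ridge(panel, "cmp", seed=11)
        assert m1.lam == m2.lam
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_too_few_ccls_rejected(self):
        panel, _ = self.linear_panel(n=10)
        with pytest.raises(ValueError, match="< 20"):
            dm.train_ridge(panel, "cmp")

    def test_rescaling_one_gene_leaves_predictions_invariant(self):
        panel, x = self.linear_panel(noise=0.1, seed=3)
        m1 = dm.train_ridge(panel, "cmp", seed=0)
        scaled = make_panel(panel.auc.copy(), panel.ccl_expr.values.copy())
        scaled.ccl_expr.values.loc["G_noise"] = (
            panel.ccl_expr.values.loc["G_noise"] * 7.0 + 3.0
        )
        m2 = dm.train_ridge(scaled, "cmp", seed=0)
        p1 = m1.predict(panel.ccl_expr.values)
        p2 = m2.predict(scaled.ccl_expr.values)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)


class TestPredict:
    def test_training_profile_reproduces_fitted_value(self):
        rng = np.random.default_rng(2)
        ccls = [f"C{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.uniform(0, 1, (3, 30)), index=["G1", "G2", "G3"], columns=ccls
        )
        auc = pd.DataFrame({"cmp": rng.uniform(1, 3, 30)}, index=ccls)
        panel = make_panel(auc, expr)
        model = dm.train_ridge(panel, "cmp", seed=0)
        clinical = ExpressionMatrix(expr[["C0"]].rename(columns={"C0": "T1"}), "log2tpm")
        est = dm.predict_auc({"cmp": model}, clinical)
        fitted = model.predict(expr[["C0"]])
        assert est.estimates.loc["T1", "cmp"] == pytest.approx(fitted.iloc[0])

    def test_all_mean_profile_predicts_intercept(self):
        rng = np.random.default_rng(4)
        ccls = [f"C{i}" for i in range(25)]
        expr = pd.DataFrame(
            rng.uniform(0, 1, (2, 25)), index=["G1", "G2"], columns=ccls
        )
        auc = pd.DataFrame({"cmp": rng.uniform(1, 3, 25)}, index=ccls)
        panel = make_panel(auc, expr)
        model = dm.train_ridge(panel, "cmp", seed=0)
        mean_prof = pd.DataFrame(
            expr.mean(axis=1).to_numpy()[:, None], index=["G1", "G2"], columns=["T1"]
        )
        est = dm.predict_auc({"cmp": model}, ExpressionMatrix(mean_prof, "log2tpm"))
        assert est.estimates.loc["T1", "cmp"] == pytest.approx(model.intercept)

    def test_gene_overlap_floor(self):
        rng = np.random.default_rng(5)
        ccls = [f"C{i}" for i in range(25)]
        expr = pd.DataFrame(
            rng.uniform(0, 1, (4, 25)),
            index=["G1", "G2", "G3", "G4"],
            columns=ccls,
        )
        auc = pd.DataFrame({"cmp": rng.uniform(1, 3, 25)}, index=ccls)
        model = dm.train_ridge(make_panel(auc, expr), "cmp", seed=0)
        clinical = pd.DataFrame({"T1": [0.5]}, index=["G1"])  # 1/4 genes present
        with pytest.raises(ValueError, match="model genes"):
            model.predict(clinical)


class TestDifferentialResponse:
    def make_est(self, mut_vals, wt_vals):
        idx = [f"M{i}" for i in range(len(mut_vals))] + [
            f"W{i}" for i in range(len(wt_vals))
        ]
        est = pd.DataFrame({"cmp": list(mut_vals) + list(wt_vals)}, index=idx)
        status = pd.Series(
            [1] * len(mut_vals) + [0] * len(wt_vals), index=idx
        )
        return est, status

    def test_exact_small_sample_not_significant(self):
        est, status = self.make_est([0.2, 0.3, 0.25], [0.8, 0.9, 0.85])
        out = dm.differential_response(est, status)
        assert out.loc[0, "logfc"] < 0
        assert out.loc[0, "p_value"] == pytest.approx(0.1)
        assert not out.loc[0, "sl_flag"]

    def test_equal_means_never_flagged(self):
        est, status = self.make_est([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        out = dm.differential_response(est, status)
        assert out.loc[0, "logfc"] == pytest.approx(0.0)
        assert not out.loc[0, "sl_flag"]

    def test_higher_auc_in_mutants_never_flagged(self):
        rng = np.random.default_rng(0)
        est, status = self.make_est(
            rng.uniform(2, 3, 30), rng.uniform(0.5, 1.0, 30)
        )
        out = dm.differential_response(est, status)
        assert out.loc[0, "p_value"] < 0.05
        assert not out.loc[0, "sl_flag"]

    def test_nonpositive_mean_skipped_with_warning(self):
        est, status = self.make_est([-1.0, -1.0, -1.0], [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="non-positive"):
            out = dm.differential_response(est, status)
        assert len(out) == 0

    def test_group_size_floor(self):
        est, status = self.make_est([0.5, 0.6], [1.0, 1.1, 1.2])
        with pytest.raises(ValueError, match=">= 3"):
            dm.differential_response(est, status)


def test_filter_predictive_drops_noise_models():
    good = dm.RidgeModel("g", ["G"], np.zeros(1), np.ones(1), np.ones(1), 0.0, 1.0, 0.5, 0.4)
    bad = dm.RidgeModel("b", ["G"], np.zeros(1), np.ones(1), np.zeros(1), 0.0, 1.0, 1.0, -0.02)
    kept = dm.filter_predictive({"g": good, "b": bad})
    assert list(kept) == ["g"]
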