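import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ptrseq import ptr_model as pm


def _xy(n=200, p=4, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)],
                     index=[f"g{i}" for i in range(n)])
    beta = rng.normal(size=p)
    y = X.to_numpy() @ beta + rng.normal(scale=noise, size=n)
    return X, pd.Series(y, index=X.index), beta


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(pm.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert pm.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(pm.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.bh_adjust([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            q = pm.bh_adjust(p)
            # brute-force step-up definition
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [m * p[j] / (np.searchsorted(np.sort(p), p[j], "right"))
                              for j in order[rank_pos:]]
                expected[idx] = min(1.0, min(m * p[order[k]] / (k + 1)
                                             for k in range(rank_pos, m)))
            np.testing.assert_allclose(q, expected, rtol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], rtol=1e-10)


class TestTissueModels:
    def test_exact_linear_relationship(self):
        X = pd.DataFrame({"x": np.arange(10.0)}, index=[f"g{i}" for i in range(10)])
        Y = pd.DataFrame({"liver": 1.0 + 2.0 * X["x"]})
        fit = pm.fit_tissue_models(Y, X)
        assert fit.intercepts["liver"] == pytest.approx(1.0)
        assert fit.coefficients.loc["x", "liver"] == pytest.approx(2.0)
        np.testing.assert_allclose(fit.residuals["liver"], 0.0, atol=1e-10)

    def test_gene_order_invariance(self):
        X, y, _ = _xy()
        Y = pd.DataFrame({"t": y})
        fit = pm.fit_tissue_models(Y, X)
        perm = np.random.default_rng(1).permutation(len(X))
        fit2 = pm.fit_tissue_models(Y.iloc[perm], X.iloc[perm])
        pd.testing.assert_frame_equal(fit.coefficients, fit2.coefficients)

    def test_matches_statsmodels_ols(self):
        X, y, _ = _xy(seed=3)
        Y = pd.DataFrame({"t": y})
        fit = pm.fit_tissue_models(Y, X)
        ref = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(fit.coefficients["t"], ref.params[1:], rtol=1e-9)
        np.testing.assert_allclose(fit.standard_errors["t"], ref.bse[1:], rtol=1e-9)
        np.testing.assert_allclose(fit.p_values["t"], ref.pvalues[1:], rtol=1e-8)

    def test_rank_deficiency_names_aliased_column(self):
        X, y, _ = _xy()
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(pm.RankDeficientError) as err:
            pm.fit_tissue_models(pd.DataFrame({"t": y}), X)
        assert err.value.aliased

    def test_missing_rows_dropped_per_tissue(self):
        X, y, _ = _xy(n=100)
        Y = pd.DataFrame({"a": y, "b": y.where(y.index != "g0")})
        fit = pm.fit_tissue_models(Y, X)
        assert fit.n_used["a"] == 100 and fit.n_used["b"] == 99


class TestSharedModel:
    def test_offset_tissues_share_slope(self):
        X = pd.DataFrame({"x": np.linspace(0, 1, 50)}, index=[f"g{i}" for i in range(50)])
        Y = pd.DataFrame({"a": 3.0 * X["x"], "b": 3.0 * X["x"] + 0.7})
        fit = pm.fit_shared_model(Y, X)
        assert fit.coefficients.loc["x", "shared"] == pytest.approx(3.0)
        assert fit.intercepts["b"] - fit.intercepts["a"] == pytest.approx(0.7)

    def test_single_tissue_reduces_to_tissue_fit(self):
        X, y, _ = _xy(seed=5)
        Y = pd.DataFrame({"t": y})
        shared = pm.fit_shared_model(Y, X)
        per_tissue = pm.fit_tissue_models(Y, X)
        np.testing.assert_allclose(shared.coefficients["shared"],
                                   per_tissue.coefficients["t"], rtol=1e-9)
        np.testing.assert_allclose(shared.standard_errors["shared"],
                                   per_tissue.standard_errors["t"], rtol=1e-9)

    def test_identical_tissues_equal_single_tissue_beta(self):
        X, y, _ = _xy(seed=6)
        Y = pd.DataFrame({"a": y, "b": y})
        shared = pm.fit_shared_model(Y, X)
        single = pm.fit_tissue_models(pd.DataFrame({"a": y}), X)
        np.testing.assert_allclose(shared.coefficients["shared"],
                                   single.coefficients["a"], rtol=1e-9)


class TestPtrAi:
    def test_definition(self):
        coef = pd.DataFrame({"t": [np.log10(2.0), 0.0, -np.log10(2.0)]},
                            index=["codon:AAA", "codon:AAC", "codon:AAG"])
        fit = pm.FitResult(coef, coef, coef, coef, coef, pd.Series(), pd.DataFrame(),
                           pd.Series())
        table = pm.ptr_ai(tissue_fit=fit)
        np.testing.assert_allclose(table.per_tissue["t"], [2.0, 1.0, 0.5])

    def test_missing_codon_columns_error(self):
        coef = pd.DataFrame({"t": [1.0]}, index=["x"])
        fit = pm.FitResult(coef, coef, coef, coef, coef, pd.Series(), pd.DataFrame(),
                           pd.Series())
        with pytest.raises(ValueError):
            pm.ptr_ai(tissue_fit=fit)


class TestCrossValidation:
    def test_noiseless_r2_near_one(self):
        X, y, _ = _xy(n=300, noise=0.0)
        cv = pm.cv_explained_variance(pd.DataFrame({"t": y}), X, folds=5, seed=0)
        assert cv.r2["t"] > 0.999

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(500, 3)), index=[f"g{i}" for i in range(500)])
        y = pd.Series(rng.normal(size=500), index=X.index)
        cv = pm.cv_explained_variance(pd.DataFrame({"t": y}), X, folds=10, seed=0)
        assert cv.r2["t"] < 0.05

    def test_folds_partition_genes(self):
        X, y, _ = _xy(n=100)
        cv = pm.cv_explained_variance(pd.DataFrame({"t": y}), X, folds=10, seed=1)
        assert sorted(cv.fold_assignment.index) == sorted(X.index)
        assert set(cv.fold_assignment) == set(range(10))

    def test_group_decomposition(self):
        rng = np.random.default_rng(8)
        n = 600
        X = pd.DataFrame({
            "s1": rng.normal(size=n), "s2": rng.normal(size=n),
            "noise1": rng.normal(size=n),
        }, index=[f"g{i}" for i in range(n)])
        y = X["s1"] + X["s2"] + rng.normal(scale=1.0, size=n)
        groups = pd.Series({"s1": "sig", "s2": "sig", "noise1": "junk"})
        r2 = pm.explained_variance_by_group(pd.DataFrame({"t": y}), X, groups,
                                            folds=5, seed=0)
        assert r2.loc["sig", "t"] > 0.5
        assert abs(r2.loc["junk", "t"]) < 0.05
        assert r2.loc["ALL", "t"] == pytest.approx(r2.loc["sig", "t"], abs=0.05)


class TestCorrectedEffect:
    def test_frisch_waugh_equals_joint_coefficient(self):
        """Double residualization reproduces the joint OLS coefficient on
        random (correlated) designs."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n, p = 120, 5
            base = rng.normal(size=(n, p))
            X = pd.DataFrame(base @ rng.normal(size=(p, p)),  # correlated columns
                             columns=[f"x{i}" for i in range(p)])
            y = pd.Series(X.to_numpy() @ rng.normal(size=p) + rng.normal(size=n))
            res = pm.corrected_effect(y, X, ["x2"])
            joint = sm.OLS(y, sm.add_constant(X)).fit()
            assert abs(res.loc["x2", "beta"] - joint.params["x2"]) < 1e-8
            assert res.loc["x2", "se"] == pytest.approx(joint.bse["x2"], rel=1e-8)

    def test_empty_covariates_equal_marginal_slope(self):
        X, y, _ = _xy(p=1, seed=10)
        res = pm.corrected_effect(y, X, ["x0"])
        marginal = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.loc["x0", "beta"] == pytest.approx(marginal.params["x0"], rel=1e-10)

    def test_single_position_scan_q_equals_p(self):
        X, y, _ = _xy(p=3, seed=11)
        scan = pm.positional_scan(y, X[["x0", "x1"]], X[["x2"]])
        assert scan.loc["x2", "q"] == pytest.approx(scan.loc["x2", "p"])

    def test_scan_orders_and_adjusts(self):
        rng = np.random.default_rng(12)
        n = 300
        base = pd.DataFrame({"c": rng.normal(size=n)})
        positions = pd.DataFrame(rng.normal(size=(n, 6)),
                                 columns=[f"pos{i}" for i in range(6)])
        y = pd.Series(2.0 * positions["pos3"] + rng.normal(size=n))
        scan = pm.positional_scan(y, base, positions)
        assert scan["q"].idxmin() == "pos3"
        assert (scan["q"] >= scan["p"] - 1e-15).all()


class TestLassoSelect:
    def test_planted_indicator_selected_among_nulls(self):
        rng = np.random.default_rng(13)
        n, p = 500, 60
        candidates = pd.DataFrame((rng.random((n, p)) < 0.3).astype(float),
                                  columns=[f"c{i}" for i in range(p)])
        y = pd.Series(0.8 * candidates["c7"] + rng.normal(scale=0.5, size=n))
        selected = pm.lasso_select(y, candidates, folds=5, seed=0)
        assert "c7" in selected

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(14)
        candidates = pd.DataFrame({"const": np.ones(100), "x": rng.normal(size=100)})
        y = pd.Series(rng.normal(size=100))
        with pytest.warns(UserWarning, match="constant"):
            pm.lasso_select(y, candidates, folds=5)


class TestExtendedCovariates:
    def test_count_transform(self):
        idx = pd.Index(["g1", "g2", "g3"])
        tables = {"ptm": pd.DataFrame({"n_mod": [0, 1, 3]}, index=idx)}
        out = pm.extended_covariates(tables, {"ptm": "count"}, idx)
        np.testing.assert_allclose(out["ptm:n_mod"], [0.0, 1.0, 2.0])

    def test_rank_two_block_keeps_two_components(self):
        rng = np.random.default_rng(15)
        idx = pd.Index([f"g{i}" for i in range(60)])
        u = rng.random(60) < 0.5
        v = rng.random(60) < 0.5
        block = pd.DataFrame(
            np.column_stack([u, u, v, v, u ^ v]).astype(float), index=idx)
        block = block.iloc[:, :4]  # exactly rank 2 (plus mean)
        out = pm.extended_covariates({"b": block}, {"b": "pca_block"}, idx)
        assert out.shape[1] == 2

    def test_binary_passthrough_and_join_warning(self):
        idx = pd.Index(["g1", "g2", "g3"])
        table = pd.DataFrame({"t": [1.0, 0.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="absent"):
            out = pm.extended_covariates({"rbp": table}, {"rbp": "binary"}, idx)
        assert list(out.columns) == ["rbp:t"]
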