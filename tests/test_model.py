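import itertools

import numpy as np
import pandas as pd
import pytest

from scapmorph.model import (
    CSAPredictorModel,
    ModelBuildError,
    aic_gaussian,
    collinearity_loop,
    diagnostics,
    drop_one,
    loocv_best_subset,
    pearson_screen,
    vif,
)
from scapmorph.synthetic import CohortSimSpec, generate_cohort_table


def _fixture_12x4(seed=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 4))
    y = 2.0 * X[:, 1] - 1.0 * X[:, 3] + rng.normal(0, 0.5, 12)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(4)])
    df["CSA"] = y
    return df


def _literal_loocv_best_subset(df, max_size, reselect=True):
    """Brute-force oracle: explicit refits for every fold and subset."""
    X = df.drop(columns="CSA").to_numpy()
    y = df["CSA"].to_numpy()
    n, p = X.shape

    def fit_rss(rows, sub):
        A = np.column_stack([np.ones(len(rows)), X[np.ix_(rows, list(sub))]])
        beta, *_ = np.linalg.lstsq(A, y[rows], rcond=None)
        return float(((y[rows] - A @ beta) ** 2).sum()), beta

    mse, best_full = {}, {}
    for k in range(1, max_size + 1):
        rss_all = {s: fit_rss(list(range(n)), s)[0]
                   for s in itertools.combinations(range(p), k)}
        best_full[k] = min(rss_all, key=lambda s: (rss_all[s], s))
        errs = []
        for i in range(n):
            tr = [j for j in range(n) if j != i]
            if reselect:
                sub = min(
                    itertools.combinations(range(p), k),
                    key=lambda s: (fit_rss(tr, s)[0], s),
                )
            else:
                sub = best_full[k]
            _, beta = fit_rss(tr, sub)
            pred = np.concatenate([[1.0], X[i, list(sub)]]) @ beta
            errs.append((y[i] - pred) ** 2)
        mse[k] = float(np.mean(errs))
    return mse, best_full


class TestPearsonScreen:
    def test_exact_linear_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": rng.normal(size=30), "x2": rng.normal(size=30)})
        df["CSA"] = 2.0 * df["x1"]
        r = pearson_screen(df)
        assert r["x1"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_predictor_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "x1": rng.normal(size=10_000), "x2": rng.normal(size=10_000)
        })
        df["CSA"] = df["x1"] + rng.normal(size=10_000)
        assert abs(pearson_screen(df)["x2"]) < 0.05

    def test_matches_textbook_formula_on_small_fixture(self):
        df = pd.DataFrame({"x1": [1.0, 2, 4, 5, 9], "CSA": [2.0, 1, 5, 4, 8]})
        x, y = df["x1"].to_numpy(), df["CSA"].to_numpy()
        want = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pearson_screen(df)["x1"] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_column_rejected_by_name(self):
        df = pd.DataFrame({"flat": np.ones(10), "CSA": np.arange(10.0)})
        with pytest.raises(ModelBuildError, match="flat"):
            pearson_screen(df)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(2)
        # orthonormal columns that are also orthogonal to the intercept
        Q, _ = np.linalg.qr(np.column_stack([np.ones(40), rng.normal(size=(40, 4))]))
        df = pd.DataFrame(Q[:, 1:], columns=list("abcd"))
        v = vif(df)
        assert np.allclose(v.to_numpy(), 1.0, atol=1e-9)

    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = 0.7 * a + rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": b})
        r = np.corrcoef(a, b)[0, 1]
        want = 1.0 / (1.0 - r**2)
        v = vif(df)
        assert v["a"] == pytest.approx(want, rel=1e-9)
        assert v["b"] == pytest.approx(want, rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        a = np.arange(10.0)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": np.random.default_rng(0).normal(size=10)})
        with pytest.raises(ModelBuildError, match="rank"):
            vif(df)


class TestSubsetSelection:
    def test_noiseless_single_active_predictor(self):
        spec = CohortSimSpec(
            n_subjects=30, n_predictors=6, active_set=(0,),
            coefficients=(1.5,), noise_sd=0.0, seed=4,
        )
        df, _ = generate_cohort_table(spec)
        res = loocv_best_subset(df, max_size=3)
        assert res.optimal_size == 1
        assert res.selected_variables == ["x1"]
        assert res.mse_by_size[1] == pytest.approx(0.0, abs=1e-16)

    def test_matches_bruteforce_oracle_with_per_fold_reselection(self):
        df = _fixture_12x4()
        res = loocv_best_subset(df, max_size=4)
        mse_o, best_o = _literal_loocv_best_subset(df, 4, reselect=True)
        for k in range(1, 5):
            assert res.mse_by_size[k] == pytest.approx(mse_o[k], rel=1e-9)
        sel = tuple(sorted(df.columns.get_loc(c) for c in res.selected_variables))
        assert sel == tuple(sorted(best_o[res.optimal_size]))

    def test_fixed_subset_mode_matches_leverage_identity_oracle(self):
        df = _fixture_12x4()
        res = loocv_best_subset(df, max_size=4, cv="fixed")
        mse_o, _ = _literal_loocv_best_subset(df, 4, reselect=False)
        for k in range(1, 5):
            assert res.mse_by_size[k] == pytest.approx(mse_o[k], rel=1e-9)

    def test_honest_and_fixed_cv_disagree_when_selection_is_unstable(self):
        # small n and correlated noise make per-fold reselection matter
        rng = np.random.default_rng(8)
        X = rng.normal(size=(14, 5))
        y = 0.6 * X[:, 0] + 0.55 * X[:, 1] + rng.normal(0, 2.0, 14)
        df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(5)])
        df["CSA"] = y
        h = loocv_best_subset(df, max_size=4, cv="honest").mse_by_size
        f = loocv_best_subset(df, max_size=4, cv="fixed").mse_by_size
        assert any(abs(h[k] - f[k]) > 1e-9 for k in range(1, 5))

    def test_row_order_invariance(self):
        df = _fixture_12x4()
        res1 = loocv_best_subset(df, max_size=3)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = loocv_best_subset(shuffled, max_size=3)
        assert np.allclose(res1.mse_by_size, res2.mse_by_size, rtol=1e-9)
        assert res1.selected_variables == res2.selected_variables

    def test_rescaling_invariance_up_to_coefficient_rescaling(self):
        df = _fixture_12x4()
        res1 = loocv_best_subset(df, max_size=3)
        df2 = df.copy()
        df2["x2"] = df2["x2"] * 10.0
        res2 = loocv_best_subset(df2, max_size=3)
        assert np.allclose(res1.mse_by_size, res2.mse_by_size, rtol=1e-9)
        assert res1.selected_variables == res2.selected_variables
        if "x2" in res1.selected_variables:
            assert res2.coefficients.loc["x2", "estimate"] == pytest.approx(
                res1.coefficients.loc["x2", "estimate"] / 10.0, rel=1e-9
            )

    def test_selected_model_beats_same_size_subsets_in_sample(self):
        df = _fixture_12x4()
        res = loocv_best_subset(df, max_size=3)
        X = df.drop(columns="CSA").to_numpy()
        y = df["CSA"].to_numpy()
        n = len(y)
        k = res.optimal_size
        best = None
        for sub in itertools.combinations(range(X.shape[1]), k):
            A = np.column_stack([np.ones(n), X[:, sub]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((y - A @ beta) ** 2).sum())
            best = rss if best is None else min(best, rss)
        assert res.full_model_mse * n == pytest.approx(best, rel=1e-9)

    def test_consistency_ladder_recovers_active_set(self):
        """In the vanishing-noise limit the selection recovers the true
        active set exactly at every cohort size (smaller interpolating
        models cannot exist, larger ones tie and lose to parsimony); with
        noise, the active set is still never missed (no underselection)."""
        for n in (50, 100, 200, 400):
            spec = CohortSimSpec(
                n_subjects=n, active_set=(0, 3, 9),
                coefficients=(0.9, 40.0, -0.3), noise_sd=0.0, seed=n,
            )
            df, truth = generate_cohort_table(spec)
            names = sorted(df.columns[list(truth.active_set)])
            res = loocv_best_subset(df, max_size=5)
            assert sorted(res.selected_variables) == names
            assert res.mse_by_size[2] > 1e-6  # too-small models misfit
        spec = CohortSimSpec(
            n_subjects=400, active_set=(0, 3, 9),
            coefficients=(0.9, 40.0, -0.3), noise_sd=1.0, seed=400,
        )
        df, truth = generate_cohort_table(spec)
        names = set(df.columns[list(truth.active_set)])
        res = loocv_best_subset(df, max_size=5)
        assert names <= set(res.selected_variables)

    def test_budget_and_size_guards(self):
        rng = np.random.default_rng(0)
        big = pd.DataFrame(rng.normal(size=(30, 21)),
                           columns=[f"x{i}" for i in range(21)])
        big["CSA"] = rng.normal(size=30)
        with pytest.raises(ModelBuildError, match="budget"):
            CSAPredictorModel(big)
        df = _fixture_12x4()
        with pytest.raises(ModelBuildError, match="max_size"):
            loocv_best_subset(df, max_size=11)

    def test_summary_mentions_key_quantities(self):
        res = loocv_best_subset(_fixture_12x4(), max_size=3)
        text = res.summary()
        assert "optimal size" in text
        assert "adjusted R2" in text
        for v in res.selected_variables:
            assert v in text


class TestCollinearityLoop:
    def test_no_flagged_variables_single_run(self):
        df = _fixture_12x4()
        res, trace = collinearity_loop(df, vif_threshold=10.0, max_size=3)
        assert res.removed_collinear == []
        assert len(trace) == 1

    def test_near_duplicate_column_is_not_co_selected(self):
        spec = CohortSimSpec(
            n_subjects=150, n_predictors=8, active_set=(0,),
            coefficients=(2.0,), noise_sd=0.5, seed=9,
            collinear_groups=(((0, 1), 0.999),),
        )
        df, _ = generate_cohort_table(spec)
        res, trace = collinearity_loop(df, vif_threshold=10.0, max_size=4)
        assert len(trace) == 3  # baseline + two flagged removals
        assert not {"x1", "x2"} <= set(res.selected_variables)

    def test_mutually_collinear_triplet_reduced_to_informative_member(self):
        spec = CohortSimSpec(
            n_subjects=200, n_predictors=10, active_set=(4,),
            coefficients=(1.5,), noise_sd=0.0, seed=10,
            collinear_groups=(((4, 5, 6), 0.97),),
        )
        df, _ = generate_cohort_table(spec)
        res, _ = collinearity_loop(df, vif_threshold=10.0, max_size=4)
        assert len({"x5", "x6", "x7"} & set(res.selected_variables)) <= 1


class TestDropOne:
    def test_aic_matches_hand_formula(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3))
        y = X[:, 0] + rng.normal(0, 0.3, 10)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["CSA"] = y
        res = loocv_best_subset(df, max_size=3)
        rep = drop_one(res)
        for v in res.selected_variables:
            keep = [c for c in res.selected_variables if c != v]
            A = np.column_stack([np.ones(10), df[keep].to_numpy()])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((y - A @ beta) ** 2).sum())
            want = 10 * np.log(rss / 10) + 2 * (len(keep) + 2)
            assert rep.table.loc[v, "aic"] == pytest.approx(want, abs=1e-9)

    def test_removing_noise_variable_does_not_hurt_adjusted_r2(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 3))
        y = 2.0 * X[:, 0] + rng.normal(0, 1.0, 60)
        df = pd.DataFrame(X, columns=["signal", "noise1", "noise2"])
        df["CSA"] = y
        import statsmodels.api as sm

        full = sm.OLS(y, sm.add_constant(df[["signal", "noise1"]])).fit()
        res = loocv_best_subset(df, max_size=3)
        if "noise1" in res.selected_variables:
            rep = drop_one(res)
            assert rep.table.loc["noise1", "adj_r2"] >= full.rsquared_adj - 0.05

    def test_largest_effect_ranks_first(self):
        spec = CohortSimSpec(
            n_subjects=200, active_set=(0, 9, 13),
            coefficients=(0.9, -0.8, 5.0), noise_sd=2.0, seed=13,
        )
        df, truth = generate_cohort_table(spec)
        res = loocv_best_subset(df, max_size=5)
        dominant = df.columns[13]  # |coef·SD| = 5.0·9.37, far above the rest
        assert dominant in res.selected_variables
        assert drop_one(res).ranking[0] == dominant


class TestDiagnostics:
    def test_gaussian_cohort_passes_normality(self):
        spec = CohortSimSpec(n_subjects=200, active_set=(0,),
                             coefficients=(1.0,), noise_sd=2.0, seed=14)
        df, _ = generate_cohort_table(spec)
        res = loocv_best_subset(df, max_size=3)
        rep = diagnostics(res)
        assert rep.probplot_r > 0.98
        assert abs(rep.residuals.sum()) < 1e-8 * len(df)
        assert not rep.heteroscedastic

    def test_heteroscedastic_noise_is_flagged(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(1.0, 10.0, 300)
        y = 3.0 * x + rng.normal(0, 1.0, 300) * x
        df = pd.DataFrame({"x1": x, "x2": rng.normal(size=300), "CSA": y})
        res = loocv_best_subset(df, max_size=2)
        rep = diagnostics(res)
        assert rep.het_abs_resid_corr > 0.3
        assert rep.heteroscedastic

    def test_plot_file_written(self, tmp_path):
        df = _fixture_12x4()
        res = loocv_best_subset(df, max_size=2)
        path = tmp_path / "diag.png"
        diagnostics(res).plot(path)
        assert path.exists() and path.stat().st_size > 0


class TestAicGaussian:
    def test_formula_value(self):
        assert aic_gaussian(10.0, 20, 3) == pytest.approx(
            20 * np.log(0.5) + 10.0, abs=1e-12
        )

    def test_monotone_in_rss(self):
        assert aic_gaussian(5.0, 20, 3) < aic_gaussian(10.0, 20, 3)
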