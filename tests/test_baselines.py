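"""Clinical logistic model and the radiomics selection chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from lvifusion.baselines import (
    REFERENCE_COUNTS,
    SelectionConfig,
    build_reference_table,
    correlation_prune,
    expand_counts,
    fit_multivariate_logistic,
    fit_univariate_logistic,
    lasso_cv_select,
    lasso_fit,
    radiomics_pipeline,
    score_clinical,
    screen_univariate,
    univariate_filter,
    zscore_normalize,
)


class TestUnivariateLogistic:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(5, 50)] * 4))
    def test_binary_or_equals_cross_product_ratio(self, cells):
        a, b, c, d = cells  # neg: unexposed/exposed; pos: unexposed/exposed
        x, y = expand_counts([a, b], [c, d], binary=True)
        fit = fit_univariate_logistic(x, y)
        assert fit.odds_ratio == pytest.approx((d * a) / (c * b), rel=1e-8)

    def test_balanced_table_gives_unit_or(self):
        x, y = expand_counts([10, 10], [10, 10], binary=True)
        fit = fit_univariate_logistic(x, y)
        assert fit.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_complete_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        fit = fit_univariate_logistic(x, y)
        assert fit.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_univariate_logistic([0.0, 1.0], [1, 1])


class TestScreening:
    def test_alpha_extremes(self):
        table, y = build_reference_table()
        assert screen_univariate(table, y, alpha=0.0)[0] == []
        assert screen_univariate(table, y, alpha=1.0)[0] == list(table.columns)

    def test_reference_counts_select_four_features(self):
        table, y = build_reference_table()
        selected, _ = screen_univariate(table, y, alpha=0.1)
        assert selected == [
            "peritumoral_edema",
            "internal_enhancement",
            "adjacent_vessel_sign",
            "dwi_rim_sign",
        ]


class TestMultivariateLogistic:
    def test_single_covariate_reduces_to_univariate(self):
        x, y = expand_counts(REFERENCE_COUNTS["peritumoral_edema"]["neg"],
                             REFERENCE_COUNTS["peritumoral_edema"]["pos"], binary=True)
        uni = fit_univariate_logistic(x, y)
        multi = fit_multivariate_logistic(pd.DataFrame({"edema": x}), y)
        assert multi.results[0].coef == pytest.approx(uni.coef, abs=1e-6)

    def test_simulation_recovery_within_3se(self):
        rng = np.random.default_rng(17)
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        p = expit(-0.5 + 1.0 * x1 + 0.5 * x2)
        y = (rng.random(n) < p).astype(int)
        model = fit_multivariate_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y)
        for res, beta in zip(model.results, (1.0, 0.5)):
            assert abs(res.coef - beta) < 3 * res.se

    def test_perfect_collinearity_rejected(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(int)
        with pytest.raises(ValueError):
            fit_multivariate_logistic(pd.DataFrame({"a": x, "b": x}), y)

    def test_score_clinical_matches_logistic_formula(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(0.8 * x)).astype(int)
        model = fit_multivariate_logistic(pd.DataFrame({"x": x}), y)
        new = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        want = expit(model.intercept + model.coefs[0] * new["x"].to_numpy())
        assert np.allclose(score_clinical(model, new), want, atol=1e-12)
        assert np.all(np.diff(score_clinical(model, new)) > 0)  # monotone


class TestZScore:
    def test_arithmetic(self):
        z, _ = zscore_normalize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["a"].to_numpy(), [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert z["a"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            z, scaler = zscore_normalize(pd.DataFrame({"a": [1.0, 2.0], "c": [5.0, 5.0]}))
        assert list(z.columns) == ["a"] and scaler.dropped == ["c"]

    def test_renormalizing_normalized_data_is_noop(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        z1, _ = zscore_normalize(df)
        z2, _ = zscore_normalize(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestUnivariateFilter:
    def test_signal_retained_and_alpha_zero_empty(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        df = pd.DataFrame({"sig": y + rng.normal(0, 0.05, 100), "noise": rng.normal(size=100)})
        kept, _ = univariate_filter(df, y, alpha=0.01)
        assert "sig" in kept
        assert univariate_filter(df, y, alpha=0.0)[0] == []

    def test_type_i_rate_on_pure_noise(self):
        rng = np.random.default_rng(8)
        n, m = 150, 1000
        y = (rng.random(n) < 0.3).astype(int)
        df = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"f{i}" for i in range(m)])
        kept, _ = univariate_filter(df, y, alpha=0.01)
        # binomial: 10 expected, 3 SE ~ 9.4
        assert 1 <= len(kept) <= 20


class TestCorrelationPrune:
    def test_duplicate_kept_once_orthogonal_kept_all(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, removed = correlation_prune(df, threshold=0.9)
        assert kept == ["a", "c"]
        assert removed[0][:2] == ("b", "a")

    def test_no_kept_pair_exceeds_threshold_brute_force(self, rng):
        base = rng.normal(size=(120, 10))
        cols = {}
        for i in range(50):  # redundant features built from a low-rank basis
            j = i % 10
            cols[f"f{i}"] = base[:, j] + rng.normal(0, 0.15 if i >= 10 else 1e-6, 120)
        df = pd.DataFrame(cols)
        kept, _ = correlation_prune(df, threshold=0.9, kind="pearson")
        sub = df[kept].corr(method="pearson").to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert np.all(np.abs(sub) < 0.9)

    def test_lower_p_member_of_redundant_pair_survives(self, rng):
        x = rng.normal(size=80)
        df = pd.DataFrame({"worse": x + rng.normal(0, 0.01, 80), "better": x})
        kept, _ = correlation_prune(df, threshold=0.9,
                                    p_values={"better": 0.001, "worse": 0.5})
        assert kept == ["better"]


class TestLasso:
    def _sparse_problem(self, seed, n=300, m=30, k=3, beta=1.5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, m))
        eta = X[:, :k] @ np.full(k, beta)
        y = (rng.random(n) < expit(eta)).astype(int)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(m)]), y

    def test_heavy_penalty_empties_selection(self):
        df, y = self._sparse_problem(0)
        clf = lasso_fit(df, y, lam=10.0)
        assert np.count_nonzero(clf.coef_) == 0

    def test_selected_subset_of_inputs_and_path_monotone(self):
        df, y = self._sparse_problem(1)
        cfg = SelectionConfig(lasso_lambda_grid=np.logspace(-3, 0.5, 12), seed=1)
        sel = lasso_cv_select(df, y, cfg)
        assert set(sel.selected) <= set(df.columns)
        assert np.all(np.diff(sel.nonzero_path) <= 0)  # sparser as lambda grows

    def test_planted_signal_recovered_across_seeds(self):
        cfg = SelectionConfig(lasso_lambda_grid=np.logspace(-3, 0, 10), seed=0)
        hits = 0
        n_seeds = 5
        for s in range(n_seeds):
            df, y = self._sparse_problem(100 + s)
            sel = lasso_cv_select(df, y, cfg)
            hits += {"f0", "f1", "f2"} <= set(sel.selected)
        assert hits >= n_seeds - 1


def test_radiomics_pipeline_stages_are_nested(rng):
    n, m = 150, 40
    X = rng.normal(size=(n, m))
    y = (rng.random(n) < expit(1.2 * X[:, 0] - 1.0 * X[:, 1])).astype(int)
    X[:, 5] = X[:, 0] + rng.normal(0, 0.05, n)  # redundant copy of a signal
    df = pd.DataFrame(X, columns=[f"r{i}" for i in range(m)])
    model = radiomics_pipeline(df, y, SelectionConfig(
        lasso_lambda_grid=np.logspace(-3, 0, 10), seed=2))
    stages = [set(kept) for _, kept, _ in model.trace.stages]
    for earlier, later in zip(stages, stages[1:]):
        assert later <= earlier
    scores = model.score(df)
    assert np.all((scores > 0) & (scores < 1))
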