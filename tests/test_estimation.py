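"""WLS correctness against the normal-equations oracle, stepwise selection
behavior, significance flags, prediction accounting."""

import json

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from dxikit.estimation import (
    FittedModel,
    StepwiseWLS,
    WeightedLeastSquares,
    predict,
    significance_flags,
    stepwise_fit,
    wls_fit,
)
from dxikit.features import FeatureMatrix


def normal_equations(X, y, w):
    """Independent closed-form oracle: beta = (X'WX)^-1 X'Wy."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


def random_instance(rng, n, p):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    w = rng.uniform(0.1, 2.0, size=n)
    return X, y, w


class TestWLS:
    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(1)
        X, y, _ = random_instance(rng, 200, 5)
        wls = WeightedLeastSquares().fit(X, y, sample_weight=np.full(200, 0.7))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(wls.coef_, ols, rtol=1e-10)

    def test_duplicated_row_equals_doubled_weight(self):
        rng = np.random.default_rng(2)
        X, y, w = random_instance(rng, 50, 3)
        X2 = np.vstack([X, X[:1]])
        y2 = np.concatenate([y, y[:1]])
        w2 = np.concatenate([w, w[:1]])
        wd = w.copy()
        wd[0] += w[0]
        a = WeightedLeastSquares().fit(X2, y2, sample_weight=w2)
        b = WeightedLeastSquares().fit(X, y, sample_weight=wd)
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=1e-10)

    def test_three_point_closed_form(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        y = np.array([1.0, 3.0, 4.0])
        w = np.array([1.0, 2.0, 3.0])
        model = WeightedLeastSquares().fit(X, y, sample_weight=w)
        np.testing.assert_allclose(
            model.coef_, normal_equations(X, y, w), atol=1e-10
        )

    def test_collinear_column_dropped_first_kept_wins(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        X = np.hstack([X, X[:, [0]]])  # column 3 duplicates column 0
        y = rng.normal(size=100)
        model = WeightedLeastSquares().fit(X, y)
        assert model.dropped_columns_ == ["x3"]

    @pytest.mark.parametrize(
        "bad",
        [
            (np.empty((0, 2)), np.empty(0), None),
            (np.ones((3, 2)), np.array([1.0, np.nan, 2.0]), None),
            (np.ones((3, 2)), np.ones(3), np.array([1.0, 0.0, 1.0])),
        ],
    )
    def test_degenerate_inputs_rejected(self, bad):
        X, y, w = bad
        with pytest.raises(ValueError):
            WeightedLeastSquares().fit(X, y, sample_weight=w)

    def test_weighted_residuals_orthogonal_to_columns(self):
        rng = np.random.default_rng(4)
        X, y, w = random_instance(rng, 300, 8)
        model = WeightedLeastSquares().fit(X, y, sample_weight=w)
        r = y - model.predict(X)
        for j in range(8):
            assert abs(np.dot(w * r, X[:, j])) < 1e-6

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 300))
        p = int(rng.integers(2, 20))
        X, y, w = random_instance(rng, n, p)
        model = WeightedLeastSquares().fit(X, y, sample_weight=w)
        oracle = normal_equations(X, y, w)
        np.testing.assert_allclose(model.coef_, oracle, rtol=1e-8, atol=1e-8)

    def test_sparse_input_matches_dense(self):
        rng = np.random.default_rng(5)
        X, y, w = random_instance(rng, 100, 4)
        a = WeightedLeastSquares().fit(X, y, sample_weight=w)
        b = WeightedLeastSquares().fit(sp.csr_matrix(X), y, sample_weight=w)
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=1e-12)


def stepwise_problem(seed=0, n=10_000, n_null=10):
    """y = 5*x1 + noise with null candidates and a forced demographic block."""
    rng = np.random.default_rng(seed)
    forced = np.ones((n, 1))
    x1 = rng.normal(size=(n, 1))
    nulls = rng.normal(size=(n, n_null))
    X = np.hstack([forced, x1, nulls])
    y = 5.0 * x1[:, 0] + rng.normal(size=n)
    columns = ["age_sex:all"] + [f"cand_{j:02d}" for j in range(n_null + 1)]
    fm = FeatureMatrix(
        X=sp.csr_matrix(X), columns=columns,
        index=pd.MultiIndex.from_arrays(
            [np.arange(n), np.full(n, 2018)], names=["person_id", "year"]
        ),
        y=y, w=np.ones(n),
    )
    return fm


class TestStepwise:
    def test_entry_p_one_reproduces_full_fit(self):
        fm = stepwise_problem(seed=1)
        full = WeightedLeastSquares().fit(fm)
        step = StepwiseWLS(entry_p=1.0).fit(fm)
        assert set(step.columns_) == set(full.columns_)
        assert step.weighted_r2_ == pytest.approx(full.weighted_r2_, abs=1e-12)

    def test_tiny_entry_p_keeps_only_forced_block(self):
        # null problem: no candidate carries signal, so a vanishing entry
        # threshold leaves the forced block alone
        rng = np.random.default_rng(987)
        fm = stepwise_problem(seed=2)
        fm.y = rng.normal(size=fm.shape[0])
        step = StepwiseWLS(entry_p=1e-12).fit(fm)
        assert step.columns_ == ["age_sex:all"]
        assert step.result().selection_trace == []

    def test_selects_true_signal_matching_best_subset_oracle(self):
        """The selected candidate set equals what exhaustive search finds:
        cand_00 (the true signal) is the single best addition, and no other
        candidate would clear the threshold afterwards."""
        fm = stepwise_problem(seed=3)
        X = fm.X.toarray()
        y = fm.y
        # oracle part 1: cand_00 minimizes RSS among all single additions
        rss = []
        for j in range(1, X.shape[1]):
            cols = X[:, [0, j]]
            beta = np.linalg.lstsq(cols, y, rcond=None)[0]
            rss.append(np.sum((y - cols @ beta) ** 2))
        assert int(np.argmin(rss)) == 0  # candidate cand_00
        # oracle part 2: with cand_00 in, every remaining candidate's partial
        # F/t p-value stays above the entry threshold
        import scipy.stats as stats

        base_cols = X[:, [0, 1]]
        beta = np.linalg.lstsq(base_cols, y, rcond=None)[0]
        rss_base = np.sum((y - base_cols @ beta) ** 2)
        n = len(y)
        worst_p = 1.0
        for j in range(2, X.shape[1]):
            cols = np.hstack([base_cols, X[:, [j]]])
            bj = np.linalg.lstsq(cols, y, rcond=None)[0]
            rss_j = np.sum((y - cols @ bj) ** 2)
            f = (rss_base - rss_j) / (rss_j / (n - 4))
            p = stats.f.sf(f, 1, n - 4)
            worst_p = min(worst_p, p)
        assert worst_p >= 1e-4
        # the implementation agrees with the oracle
        step = StepwiseWLS(entry_p=1e-4).fit(fm)
        assert set(step.columns_) == {"age_sex:all", "cand_00"}
        assert len(step.result().selection_trace) == 1

    def test_never_retains_nonforced_above_threshold(self):
        rng = np.random.default_rng(7)
        fm = stepwise_problem(seed=8, n=2000, n_null=15)
        step = StepwiseWLS(entry_p=0.2).fit(fm)
        retained = [c for c in step.columns_ if not c.startswith("age_sex:")]
        p = dict(zip(step.columns_, step.p_values_))
        assert all(p[c] < 0.2 for c in retained)

    def test_invalid_entry_p_rejected(self):
        fm = stepwise_problem(seed=4, n=100, n_null=2)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                StepwiseWLS(entry_p=bad).fit(fm)

    def test_trace_records_entries_in_order(self):
        fm = stepwise_problem(seed=5)
        step = StepwiseWLS(entry_p=1e-4).fit(fm)
        trace = step.result().selection_trace
        assert [t["step"] for t in trace] == list(range(1, len(trace) + 1))
        assert trace[0]["column"] == "cand_00"


class TestFlagsAndPrediction:
    def make_model(self, p_values, columns=None, m=100):
        k = len(p_values)
        return FittedModel(
            columns=columns or [f"c{i}" for i in range(k)],
            coef=np.zeros(k), se=np.ones(k),
            p_values=np.asarray(p_values, dtype=float),
            weighted_r2=0.0, df_resid=10, n_obs=20, n_candidates=m,
        )

    def test_threshold_is_min_of_bonferroni_and_ceiling(self):
        model = self.make_model([1e-6, 1e-3], m=100)
        flags = significance_flags(model, alpha=0.05, m=100)
        # min(0.05/100, 1e-4) = 1e-4: only the first column clears it
        assert flags == {"c0": True, "c1": False}

    def test_boundary_p_not_flagged(self):
        model = self.make_model([0.05 / 10], m=10)
        flags = significance_flags(model, alpha=0.05, m=10, ceiling=1.0)
        assert flags == {"c0": False}

    def test_zero_p_flagged_and_bad_m_rejected(self):
        model = self.make_model([0.0])
        assert significance_flags(model, m=5)["c0"] is True
        with pytest.raises(ValueError):
            significance_flags(model, m=0)

    def test_all_zero_diag_row_predicts_cell_mean(self):
        # two cells, one diagnostic column
        X = np.array([[1, 0, 1], [1, 0, 0], [0, 1, 0], [0, 1, 1]], dtype=float)
        y = np.array([110.0, 100.0, 50.0, 80.0])
        fm = FeatureMatrix(
            X=sp.csr_matrix(X),
            columns=["age_sex:F", "age_sex:M", "dxi:item"],
            index=pd.MultiIndex.from_arrays(
                [range(4), [2018] * 4], names=["person_id", "year"]
            ),
            y=y, w=np.ones(4),
        )
        model = wls_fit(fm)
        coef = dict(zip(model.columns, model.coef))
        pred = model.predict(fm)
        assert pred[1] == pytest.approx(coef["age_sex:F"])

    def test_negative_predictions_counted_with_weights(self):
        model = FittedModel(
            columns=["a", "b"], coef=np.array([1.0, -2.0]),
            se=np.ones(2), p_values=np.zeros(2),
            weighted_r2=0.0, df_resid=1, n_obs=3,
        )
        X = sp.csr_matrix(np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))
        fm = FeatureMatrix(
            X=X, columns=["a", "b"],
            index=pd.MultiIndex.from_arrays(
                [range(3), [2018] * 3], names=["person_id", "year"]
            ),
            w=np.array([1.0, 1.0, 2.0]),
        )
        pred = predict(model, fm)
        # predictions: 1, -1, -2 with weights 1,1,2 -> negative share 3/4
        assert pred.negative_share == pytest.approx(0.75)

    def test_missing_model_column_is_an_error(self):
        model = FittedModel(
            columns=["a", "zz"], coef=np.ones(2), se=np.ones(2),
            p_values=np.zeros(2), weighted_r2=0.0, df_resid=1, n_obs=2,
        )
        fm = FeatureMatrix(
            X=sp.csr_matrix(np.ones((2, 1))), columns=["a"],
            index=pd.MultiIndex.from_arrays(
                [range(2), [2018] * 2], names=["person_id", "year"]
            ),
        )
        with pytest.raises(KeyError):
            model.predict(fm)

    def test_json_round_trip(self, tmp_path):
        fm = stepwise_problem(seed=6, n=500, n_null=3)
        model = stepwise_fit(fm, entry_p=0.5)
        path = tmp_path / "model.json"
        model.to_json(path)
        again = FittedModel.from_json(path)
        assert again.columns == model.columns
        np.testing.assert_allclose(again.coef, model.coef)
        assert again.selection_trace == model.selection_trace
        assert again.settings == model.settings
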