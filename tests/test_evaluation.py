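"""Weighted metrics against brute-force formulas, predictive ratios,
frequency-binned residuals with clustered intervals, model comparison."""

import numpy as np
import pandas as pd
import pytest

from dxikit.evaluation import (
    EvaluationReport,
    FrequencyBinning,
    compare_models,
    compute_code_frequencies,
    predictive_ratios,
    residuals_by_frequency,
    weighted_cpm,
    weighted_mae,
    weighted_r2,
)


def brute_r2(y, yhat, w):
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    rss = sum(wi * (yi - fi) ** 2 for wi, yi, fi in zip(w, y, yhat))
    tss = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    return 1 - rss / tss


def brute_mae(y, yhat, w):
    return sum(wi * abs(yi - fi) for wi, yi, fi in zip(w, y, yhat)) / sum(w)


def brute_cpm(y, yhat, w):
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    num = sum(wi * abs(yi - fi) for wi, yi, fi in zip(w, y, yhat))
    den = sum(wi * abs(yi - ybar) for wi, yi in zip(w, y))
    return 1 - num / den


class TestScalarMetrics:
    y = np.array([1.0, 4.0, 2.0, 8.0])
    yhat = np.array([1.5, 3.0, 2.5, 6.0])
    w = np.array([1.0, 2.0, 0.5, 1.5])

    def test_perfect_fit(self):
        assert weighted_r2(self.y, self.y, self.w) == 1.0
        assert weighted_mae(self.y, self.y, self.w) == 0.0
        assert weighted_cpm(self.y, self.y, self.w) == 1.0

    def test_weighted_mean_predictor_scores_zero(self):
        ybar = np.dot(self.w, self.y) / self.w.sum()
        null = np.full_like(self.y, ybar)
        assert weighted_r2(self.y, null, self.w) == pytest.approx(0.0, abs=1e-12)
        assert weighted_cpm(self.y, null, self.w) == pytest.approx(0.0, abs=1e-12)

    def test_match_brute_force_formulas(self):
        assert weighted_r2(self.y, self.yhat, self.w) == pytest.approx(
            brute_r2(self.y, self.yhat, self.w), abs=1e-12
        )
        assert weighted_mae(self.y, self.yhat, self.w) == pytest.approx(
            brute_mae(self.y, self.yhat, self.w), abs=1e-12
        )
        assert weighted_cpm(self.y, self.yhat, self.w) == pytest.approx(
            brute_cpm(self.y, self.yhat, self.w), abs=1e-12
        )

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        w = np.full(50, 3.0)
        assert weighted_r2(y, yhat, w) == pytest.approx(
            1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12
        )
        assert weighted_mae(y, yhat, w) == pytest.approx(
            np.abs(y - yhat).mean(), abs=1e-12
        )

    def test_constant_error_gives_that_mae(self):
        assert weighted_mae(self.y, self.y + 7.0, self.w) == pytest.approx(7.0)

    def test_cpm_negative_when_worse_than_mean(self):
        y = np.array([0.0, 0.0, 10.0])
        bad = np.array([100.0, -100.0, 50.0])
        assert weighted_cpm(y, bad, np.ones(3)) < 0

    def test_zero_dispersion_outcomes_rejected(self):
        flat = np.ones(4)
        with pytest.raises(ValueError):
            weighted_r2(flat, flat, np.ones(4))
        with pytest.raises(ValueError):
            weighted_cpm(flat, flat, np.ones(4))

    def test_r2_can_be_negative_out_of_sample(self):
        y = np.array([1.0, 2.0, 3.0])
        assert weighted_r2(y, y[::-1] * 5, np.ones(3)) < 0


class TestPredictiveRatios:
    def test_perfect_predictions_ratio_one(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(8, 1.5, 2000)
        w = rng.uniform(0.1, 1.0, 2000)
        table = predictive_ratios(y, y, w)
        assert np.allclose(table["predictive_ratio"].dropna(), 1.0)

    def test_mean_predictor_over_and_under_predicts_tails(self):
        rng = np.random.default_rng(2)
        y = rng.lognormal(8, 1.5, 5000)
        w = np.ones(5000)
        null = np.full(5000, y.mean())
        table = predictive_ratios(y, null, w)
        assert table["predictive_ratio"].iloc[0] > 1  # cheap bin over-paid
        assert table["predictive_ratio"].iloc[-1] < 1  # top bin under-paid

    def test_single_bin_is_overall_ratio(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([2.0, 2.0, 2.0])
        w = np.array([1.0, 1.0, 2.0])
        table = predictive_ratios(y, yhat, w, percentile_edges=())
        expected = (np.dot(w, yhat) / w.sum()) / (np.dot(w, y) / w.sum())
        assert table["predictive_ratio"].iloc[0] == pytest.approx(expected)

    def test_bin_means_conserve_overall_mean(self):
        rng = np.random.default_rng(3)
        y = rng.lognormal(8, 1.2, 3000)
        w = rng.uniform(0.2, 1.0, 3000)
        table = predictive_ratios(y, y * 0.9, w)
        overall = np.dot(w, y) / w.sum()
        recombined = (
            (table["weight"] * table["mean_actual"]).sum() / table["weight"].sum()
        )
        assert recombined == pytest.approx(overall, rel=1e-12)

    def test_bad_edges_rejected(self):
        y = np.arange(10.0) + 1
        for edges in ((0.0, 50.0), (50.0, 40.0), (101.0,)):
            with pytest.raises(ValueError):
                predictive_ratios(y, y, None, percentile_edges=edges)


class TestFrequencyResiduals:
    def binning(self):
        return FrequencyBinning(
            freq_per_million={"A100": 3.0, "B200": 450.0, "C300": 45_000.0}
        )

    def test_power_of_ten_bin_assignment(self):
        binning = self.binning()
        assert binning.exponent_of("A100") == 0   # 3 per million -> [1, 10)
        assert binning.exponent_of("B200") == 2
        assert binning.exponent_of("C300") == 4

    def test_unknown_code_routed_to_rarest_bin_and_logged(self):
        binning = self.binning()
        assert binning.exponent_of("ZZZ99") == 0
        assert binning.unknown_codes == ["ZZZ99"]

    def test_zero_residuals_give_zero_bins(self):
        table = residuals_by_frequency(
            np.zeros(3),
            [("A100",), ("B200",), ("A100", "C300")],
            self.binning(),
        )
        assert (table["mean_residual"] == 0).all()

    def test_single_bin_reproduces_overall_weighted_mean(self):
        res = np.array([10.0, -4.0, 6.0])
        w = np.array([1.0, 0.5, 2.0])
        binning = FrequencyBinning(freq_per_million={"A100": 5.0})
        table = residuals_by_frequency(
            res, [("A100",)] * 3, binning, weights=w
        )
        assert table["mean_residual"].iloc[0] == pytest.approx(
            np.dot(w, res) / w.sum()
        )

    def test_omitted_rare_effect_recovered_within_ci(self):
        """Residuals of +10,000 on carriers of a rare code land in that
        code's bin with a CI containing 10,000."""
        rng = np.random.default_rng(4)
        n = 400
        carrier = rng.random(n) < 0.1
        res = rng.normal(0, 500, n) + np.where(carrier, 10_000.0, 0.0)
        sets = [("R999",) if c else ("C300",) for c in carrier]
        binning = FrequencyBinning(
            freq_per_million={"R999": 5.0, "C300": 45_000.0}
        )
        table = residuals_by_frequency(res, sets, binning)
        rare = table.loc[FrequencyBinning.bin_label(0)]
        assert rare["ci_low"] <= 10_000.0 <= rare["ci_high"]
        assert rare["mean_residual"] == pytest.approx(10_000.0, rel=0.05)

    def test_clustered_ci_wider_for_duplicated_person(self):
        """Repeating one person's rows must not shrink the interval the way
        independent observations would."""
        rng = np.random.default_rng(5)
        res = rng.normal(0, 100, 40)
        sets = [("A100",)] * 40
        binning = FrequencyBinning(freq_per_million={"A100": 5.0})
        independent = residuals_by_frequency(
            res, sets, binning, person_ids=list(range(40))
        )
        clustered = residuals_by_frequency(
            res, sets, binning, person_ids=[i % 10 for i in range(40)]
        )
        width_i = independent["ci_high"] - independent["ci_low"]
        width_c = clustered["ci_high"] - clustered["ci_low"]
        assert width_c.iloc[0] != width_i.iloc[0]

    def test_empirical_frequencies_from_full_sample(self):
        table = pd.DataFrame(
            {"diagnosis_set": [("A100",), ("A100", "B200"), (), ("B200",)]}
        )
        binning = compute_code_frequencies(table)
        assert binning.freq_per_million["A100"] == pytest.approx(0.5e6)
        assert binning.total_enrollee_years == 4


class TestCompareModels:
    def report(self, model_id, r2=0.5, fingerprint=1):
        return EvaluationReport(
            model_id=model_id, weighted_r2=r2, weighted_mae=100.0,
            weighted_cpm=0.2, negative_share=0.01, n_rows=10, n_variables=3,
            index_fingerprint=fingerprint,
        )

    def test_single_report(self):
        table = compare_models([self.report("base")])
        assert list(table.index) == ["base"]

    def test_identical_models_zero_deltas(self):
        table = compare_models([self.report("a"), self.report("b")])
        assert table.loc["b", "delta_r2_vs_base"] == 0.0

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="different row sets"):
            compare_models(
                [self.report("a"), self.report("b", fingerprint=2)]
            )
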