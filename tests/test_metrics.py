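import numpy as np
import pytest

from simdta.metrics import (
    aupr,
    concordance_index,
    evaluate,
    mse,
    rm_squared,
    summarize_reports,
    write_reports_csv,
)

from .oracles import aupr_enumeration, ci_double_loop, rm2_regression


class TestMSE:
    def test_perfect_prediction_zero(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_residuals(self):
        assert mse([0, 0], [1, 1]) == 1.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        expected = sum((a - b) ** 2 for a, b in zip(y, yhat)) / 50
        assert mse(y, yhat) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([1, 2], [1])


class TestConcordanceIndex:
    def test_perfect_ordering_is_one(self):
        assert concordance_index([1, 2, 3], [1, 2, 3]) == 1.0

    def test_tied_predictions_score_half(self):
        assert concordance_index([1, 2], [5, 5]) == 0.5

    def test_single_swap_enumeration(self):
        # 6 ordered label pairs, one discordant -> 5/6
        assert concordance_index([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(5 / 6)

    def test_matches_double_loop_oracle(self):
        """Vectorized CI equals literal pairwise enumeration on random
        instances with label and prediction ties."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 201))
            y = np.round(rng.normal(size=n), 1)  # induce label ties
            if np.all(y == y[0]):
                continue
            yhat = np.round(rng.normal(size=n), 1)
            assert concordance_index(y, yhat) == pytest.approx(
                ci_double_loop(y, yhat)
            )

    def test_reversal_complement(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        yhat = rng.normal(size=60)  # continuous: no prediction ties
        assert concordance_index(y, yhat) + concordance_index(y, -yhat) \
            == pytest.approx(1.0)

    def test_random_predictor_concentrates_at_half(self):
        rng = np.random.default_rng(7)
        y = np.arange(100, dtype=float)
        cis = [concordance_index(y, rng.permutation(y)) for _ in range(500)]
        assert abs(np.mean(cis) - 0.5) < 0.02

    def test_all_labels_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            concordance_index([2, 2, 2], [1, 2, 3])


class TestRmSquared:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 3.5, 4.0])
        assert rm_squared(y, y) == pytest.approx(1.0)

    def test_equal_fits_collapse_to_r2(self):
        # predictions proportional to observations through the origin:
        # both fits coincide, so rm2 == r2
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = 0.5 * y
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        assert rm_squared(y, yhat) == pytest.approx(r2)

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.normal(5, 2, size=40)
            yhat = y + rng.normal(0, 1, size=40) + rng.normal(0, 0.5)
            assert rm_squared(y, yhat) == pytest.approx(rm2_regression(y, yhat))

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.normal(size=30)
            yhat = 0.5 * y + rng.normal(0, 0.7, size=30)
            r2 = np.corrcoef(y, yhat)[0, 1] ** 2
            assert rm_squared(y, yhat) <= r2 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rm_squared([1, 2, 3], [4, 4, 4])


class TestAUPR:
    def test_perfect_separation_is_one(self):
        y = np.array([8.0, 9.0, 5.0, 5.5])
        yhat = np.array([3.0, 4.0, 1.0, 2.0])
        assert aupr(y, yhat, threshold=7.0) == 1.0

    def test_single_positive_ranked_second(self):
        # one positive of two, ranked below the negative: PR point (1, 1/2)
        assert aupr([1, 0], [0.1, 0.9], threshold=0.5) == 0.5

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            y = rng.normal(7, 1, size=60)
            yhat = y + rng.normal(0, 1.5, size=60)
            labels = y >= 7.0
            if labels.all() or not labels.any():
                continue
            assert aupr(y, yhat, 7.0) == pytest.approx(
                aupr_enumeration(labels, yhat)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.normal(7, 1, size=80)
        yhat = y + rng.normal(0, 1, size=80)
        assert aupr(y, yhat, 7.0) == pytest.approx(aupr(y, np.exp(yhat), 7.0))

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(8)
        n, prevalence = 400, 0.3
        y = (np.arange(n) < prevalence * n).astype(float)
        means = [aupr(y, rng.permutation(n).astype(float), 0.5)
                 for _ in range(300)]
        assert abs(np.mean(means) - prevalence) < 0.02

    def test_low_is_strong_orientation(self):
        # raw-Kd-like scale: positives are BELOW threshold, ranking reversed
        y = np.array([10.0, 20.0, 5000.0, 9000.0])
        yhat = np.array([15.0, 30.0, 4000.0, 8000.0])
        assert aupr(y, yhat, threshold=100.0, positive_is_high=False) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            aupr([1, 2], [0.1, 0.2], threshold=0.0)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([5.0, 6.0, 7.5, 8.0])
        r = evaluate(y, y, threshold=7.0)
        assert (r.mse, r.ci, r.rm2, r.aupr) == (0.0, 1.0, 1.0, 1.0)
        assert r.n == 4

    def test_constant_predictions_give_half_ci(self):
        with pytest.warns(UserWarning):
            r = evaluate([5.0, 6.0, 8.0], [6.0, 6.0, 6.0], threshold=7.0)
        assert r.ci == 0.5
        assert np.isnan(r.rm2)

    def test_composition_matches_individual_metrics(self):
        rng = np.random.default_rng(5)
        y = rng.normal(7, 1, size=30)
        yhat = y + rng.normal(0, 0.5, size=30)
        r = evaluate(y, yhat, threshold=7.0)
        assert r.mse == mse(y, yhat)
        assert r.ci == concordance_index(y, yhat)
        assert r.rm2 == rm_squared(y, yhat)
        assert r.aupr == aupr(y, yhat, 7.0)

    def test_summary_mean_and_se_arithmetic(self, tmp_path):
        r1 = evaluate([5, 6, 8.0], [5.1, 6.2, 7.8], threshold=7.0)
        r2 = evaluate([5, 7.5, 8.0], [5.3, 7.0, 8.4], threshold=7.0)
        summary = summarize_reports([r1, r2])
        vals = np.array([r1.mse, r2.mse])
        assert summary["mse"]["mean"] == pytest.approx(vals.mean())
        assert summary["mse"]["se"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(2)
        )
        write_reports_csv([r1, r2], tmp_path / "r.csv")
        assert (tmp_path / "r.csv").read_text().count("\n") == 9  # header + 2*4
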