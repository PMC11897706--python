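"""Binned ("offset") and pointwise cross-validation for penalty selection."""

import numpy as np
import pytest

from l0seg import (
    CVConfig,
    WeightedSeries,
    binned_cv_predict,
    binned_cv_split,
    l0_segment,
    lambda_for_target_segments,
    select_lambda,
)
from l0seg.synthetic import SimSpec, sim_chip_like, sim_piecewise


class TestBinnedSplit:
    def test_length6_window2_fold1(self):
        # the canonical worked split: train {X1,X2,X5,X6}, test {X3,X4}
        train, tests = binned_cv_split(6, window=2, n_folds=3, fold=1)
        assert list(train) == [0, 1, 4, 5]
        assert len(tests) == 1
        j, pos = tests[0]
        assert j == 1 and list(pos) == [2, 3]

    def test_window1_fold0(self):
        train, tests = binned_cv_split(4, window=1, n_folds=4, fold=0)
        assert list(train) == [1, 2, 3]
        assert [list(p) for _, p in tests] == [[0]]

    def test_folds_partition_sequence(self):
        n, window, folds = 103, 7, 5
        seen = np.zeros(n, dtype=int)
        for k in range(folds):
            _, tests = binned_cv_split(n, window, folds, k)
            for _, pos in tests:
                seen[pos] += 1
        assert np.all(seen == 1)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            binned_cv_split(10, window=10, n_folds=2, fold=0)


class TestBinnedPredict:
    def test_worked_example_neighbor_average(self):
        # fitted values over train {0,1,4,5}; prediction for window 1 is
        # (fitted at position 0 + fitted at position 5) / 2
        train = np.array([0, 1, 4, 5])
        fitted = np.array([3.0, 4.0, 7.0, 9.0])
        pred = binned_cv_predict(fitted, train, window_index=1, window=2, n=6)
        assert pred == pytest.approx((3.0 + 9.0) / 2)

    def test_constant_signal_predicts_constant(self):
        train = np.array([0, 1, 4, 5])
        fitted = np.full(4, 2.5)
        assert binned_cv_predict(fitted, train, 1, 2, 6) == pytest.approx(2.5)

    def test_edge_window_uses_single_neighbor(self):
        # first window held out: only the right neighbor exists
        train, tests = binned_cv_split(6, 2, 3, 0)
        fitted = np.array([5.0, 6.0, 7.0, 8.0])  # positions 2,3,4,5
        pred = binned_cv_predict(fitted, train, window_index=0, window=2, n=6)
        # right-most point of the adjacent right window (positions 2,3) is 3
        assert pred == pytest.approx(6.0)

    def test_last_window_uses_left_neighbor(self):
        train, tests = binned_cv_split(6, 2, 3, 2)
        fitted = np.array([1.0, 2.0, 3.0, 4.0])  # positions 0,1,2,3
        pred = binned_cv_predict(fitted, train, window_index=2, window=2, n=6)
        assert pred == pytest.approx(3.0)  # left-most point of window 1 = position 2


class TestSelectLambda:
    def test_pointwise_recovers_gaussian_changepoints(self):
        spec = SimSpec(lengths=np.full(8, 150), params=np.array(
            [0.0, 5.0, 1.0, 7.0, 2.0, 9.0, 3.0, 8.0]), sd=1.0, seed=5)
        series, truth = sim_piecewise(spec, "gaussian")
        res = select_lambda(series, "gaussian", "l0",
                            CVConfig(mode="pointwise", n_folds=5))
        s = l0_segment(series, "gaussian", res.lambda_)
        from sklearn.metrics import rand_score

        lab_true = np.repeat(np.arange(8), 150)
        lab_fit = np.repeat(np.arange(s.n_segments), s.ends - s.starts)
        assert rand_score(lab_true, lab_fit) >= 0.95
        assert abs(s.n_segments - 8) <= 2

    def test_binned_cv_much_sparser_than_pointwise_on_chip_like(self):
        series, _ = sim_chip_like(n=3000, seed=0)
        res_b = select_lambda(series, "poisson", "l0",
                              CVConfig(mode="binned", window_bp=300, bin_bp=20))
        res_p = select_lambda(series, "poisson", "l0",
                              CVConfig(mode="pointwise"))
        n_b = l0_segment(series, "poisson", res_b.lambda_).n_segments
        n_p = l0_segment(series, "poisson", res_p.lambda_).n_segments
        assert n_p >= 5 * n_b

    def test_flat_noise_free_signal_selects_single_segment(self):
        series = WeightedSeries(np.full(120, 4.0))
        res = select_lambda(series, "poisson", "l0", CVConfig(mode="pointwise"))
        assert res.lambda_ == res.lambdas[-1]  # ties break to the largest
        assert l0_segment(series, "poisson", res.lambda_).n_segments == 1

    def test_training_never_sees_test_values(self):
        # corrupting the held-out positions must not change the training fit
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 60)
        train, tests = binned_cv_split(60, 1, 5, 0)
        test_pos = np.concatenate([p for _, p in tests])
        assert np.intersect1d(train, test_pos).size == 0
        y_corrupt = y.copy()
        y_corrupt[test_pos] = 1e6
        fit_a = l0_segment(y[train], "gaussian", 2.0).reconstruct()
        fit_b = l0_segment(y_corrupt[train], "gaussian", 2.0).reconstruct()
        assert np.array_equal(fit_a, fit_b)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(WeightedSeries(np.arange(10.0)), "gaussian", "l0",
                          CVConfig(mode="binned", window_bp=300, bin_bp=20))


class TestLambdaForTargetSegments:
    def test_one_segment_target(self, rng):
        y = rng.normal(0, 2, 40)
        lam = lambda_for_target_segments(y, "gaussian", "l0", 1)
        assert l0_segment(y, "gaussian", lam).n_segments == 1

    def test_per_point_target(self, rng):
        y = np.cumsum(rng.uniform(1, 2, 12))  # distinct values
        lam = lambda_for_target_segments(y, "gaussian", "l0", 12)
        assert l0_segment(y, "gaussian", lam).n_segments == 12

    def test_recovers_planted_segment_count(self):
        spec = SimSpec(lengths=np.full(10, 100),
                       params=np.linspace(2, 40, 10), seed=11)
        series, _ = sim_piecewise(spec, "poisson")
        lam = lambda_for_target_segments(series, "poisson", "l0", 10)
        assert l0_segment(series, "poisson", lam).n_segments == 10

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            lambda_for_target_segments(np.arange(5.0), "gaussian", "l0", 0)
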