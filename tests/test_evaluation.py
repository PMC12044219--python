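"""Metric closed forms and loop oracles; experiment-harness contracts."""

import numpy as np
import pytest

import lateralgait as lg
from lateralgait.evaluation import (ConfusionMatrix, evaluation_report,
                                    roc_curve_ovr)


class TestConfusion:
    def test_perfect_prediction(self):
        cm, acc = lg.confusion_and_scores([0, 1, 2, 3], [0, 1, 2, 3])
        assert acc == 1.0
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))

    def test_small_example(self):
        # truth [A,A,B,B], predicted [A,B,B,B]
        cm, acc = lg.confusion_and_scores([0, 0, 1, 1], [0, 1, 1, 1])
        assert acc == 0.75
        rec_a, _, _ = lg.recall_fpr_f1(cm.class_counts(0))
        assert rec_a == 0.5

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        cm, acc = lg.confusion_and_scores(t, p)
        expected = np.zeros((4, 4), int)
        for a, b in zip(t, p):
            expected[a, b] += 1
        np.testing.assert_array_equal(cm.counts, expected)
        assert acc == pytest.approx(np.mean(t == p), abs=1e-15)

    def test_marginals_conserve_counts(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 4, 100)
        p = rng.integers(0, 4, 100)
        cm, _ = lg.confusion_and_scores(t, p)
        assert cm.total == 100
        for c in range(4):
            cc = cm.class_counts(c)
            assert cc["tp"] + cc["fn"] == cm.counts[c].sum()
            assert cc["tp"] + cc["fp"] + cc["tn"] + cc["fn"] == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lg.confusion_and_scores([0, 1], [0])


class TestRates:
    def test_recall(self):
        r, _, _ = lg.recall_fpr_f1({"tp": 9, "fp": 0, "tn": 0, "fn": 1})
        assert r == pytest.approx(0.9)

    def test_f1(self):
        _, _, f1 = lg.recall_fpr_f1({"tp": 8, "fp": 2, "tn": 0, "fn": 2})
        assert f1 == pytest.approx(0.8)

    def test_fpr_zero_fp(self):
        _, fpr, _ = lg.recall_fpr_f1({"tp": 1, "fp": 0, "tn": 10, "fn": 0})
        assert fpr == 0.0

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            r, _, _ = lg.recall_fpr_f1({"tp": 0, "fp": 0, "tn": 5, "fn": 0})
        assert r == 0.0


class TestAuc:
    def test_perfect_separation(self):
        scores = np.eye(4)[[0, 0, 1, 1]]
        aucs = lg.roc_auc_ovr([0, 0, 1, 1], scores)
        assert aucs[0] == 1.0 and aucs[1] == 1.0

    def test_uninformative_scores(self):
        scores = np.full((8, 4), 0.25)
        aucs = lg.roc_auc_ovr([0, 1, 2, 3] * 2, scores)
        assert all(aucs[c] == 0.5 for c in range(4))

    def test_absent_class_reported_missing(self):
        aucs = lg.roc_auc_ovr([0, 0, 1, 1], np.random.rand(4, 4))
        assert aucs[2] is None and aucs[3] is None

    def test_matches_mann_whitney_brute_force(self):
        rng = np.random.default_rng(5)
        t = rng.integers(0, 4, 60)
        s = rng.random((60, 4))
        aucs = lg.roc_auc_ovr(t, s)
        for c in range(4):
            pos = s[t == c, c]
            neg = s[t != c, c]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                     for a in pos for b in neg]
            assert aucs[c] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_matches_curve_integration(self):
        rng = np.random.default_rng(6)
        t = rng.integers(0, 4, 80)
        s = rng.random((80, 4))
        aucs = lg.roc_auc_ovr(t, s)
        for c in range(4):
            fpr, tpr = roc_curve_ovr(t, s[:, c], c)
            assert np.trapezoid(tpr, fpr) == pytest.approx(aucs[c], abs=1e-9)


class TestRegressionMetrics:
    def test_rmse_examples(self):
        assert lg.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert lg.rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(12.5 ** 0.5)

    def test_rmse_oracle_and_ss_identity(self):
        rng = np.random.default_rng(7)
        m, p = rng.standard_normal(41), rng.standard_normal(41)
        expected = (sum((a - b) ** 2 for a, b in zip(m, p)) / 41) ** 0.5
        val = lg.rmse(m, p)
        assert val == pytest.approx(expected, abs=1e-12)
        # SS_res = M * RMSE^2
        assert np.sum((m - p) ** 2) == pytest.approx(41 * val ** 2)

    def test_rmse_errors(self):
        with pytest.raises(ValueError):
            lg.rmse([], [])
        with pytest.raises(ValueError):
            lg.rmse([1.0], [1.0, 2.0])

    def test_r2_closed_forms(self):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        assert lg.r_squared(m, m) == 1.0
        assert lg.r_squared(m, np.full(4, m.mean())) == 0.0
        rng = np.random.default_rng(8)
        p = rng.standard_normal(4)
        expected = 1 - np.sum((m - p) ** 2) / np.sum((m - m.mean()) ** 2)
        assert lg.r_squared(m, p) == pytest.approx(expected, abs=1e-12)

    def test_r2_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            lg.r_squared([2.0, 2.0], [1.0, 2.0])


class TestPairedT:
    def test_frozen_example(self):
        # differences [1, 2, 3]: t = 2*sqrt(3) = 3.4641, df 2;
        # two-sided p from the closed-form df=2 survival function
        # P(T>t) = 1/2 - t / (2*sqrt(2+t^2))  ->  p = 0.0742
        t, df, p = lg.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            lg.paired_t_test([1.0, 2.0], [1.0, 2.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        t1, _, p1 = lg.paired_t_test(a, b)
        t2, _, p2 = lg.paired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestHarnesses:
    def test_advance_shift_identity(self):
        X = np.arange(20).reshape(10, 2)
        y = np.arange(10)
        Xs, ys = lg.advance_shift(X, y, 0)
        np.testing.assert_array_equal(Xs, X)
        np.testing.assert_array_equal(ys, y)

    def test_advance_shift_pairs_future_labels(self):
        X = np.arange(10)[:, None]
        y = np.arange(10)
        Xs, ys = lg.advance_shift(X, y, 2)
        assert len(Xs) == 8
        np.testing.assert_array_equal(ys, y[2:])
        np.testing.assert_array_equal(Xs[:, 0], np.arange(8))

    def test_advance_shift_bounds(self):
        with pytest.raises(ValueError):
            lg.advance_shift(np.zeros((5, 1)), np.zeros(5), 5)

    def test_contiguous_fraction(self):
        x = np.arange(100)
        np.testing.assert_array_equal(lg.contiguous_fraction(x, 1.0), x)
        block = lg.contiguous_fraction(x, 0.1, offset=7)
        assert len(block) == 10
        np.testing.assert_array_equal(block, np.arange(7, 17))
        with pytest.raises(ValueError):
            lg.contiguous_fraction(x, 0.0)
        with pytest.raises(ValueError):
            lg.contiguous_fraction(x, 0.5, offset=60)

    def test_report_structure(self):
        rng = np.random.default_rng(10)
        t = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        s = rng.random((50, 4))
        rep = evaluation_report(t, p, score_matrix=s,
                                regression={"theta": (rng.standard_normal(50),
                                                      rng.standard_normal(50))})
        assert set(rep) >= {"accuracy", "confusion", "per_phase",
                            "macro_recall", "macro_f1", "auc", "macro_auc",
                            "rmse_theta", "r2_theta"}
        assert rep["macro_recall"] == pytest.approx(np.mean(
            [rep["per_phase"][k]["recall"] for k in rep["per_phase"]]))

    def test_streaming_matches_offline(self, synced):
        from lateralgait.features import WindowSpec, td_features

        spec = WindowSpec(length_ms=250, increment_ms=50)
        offline = [float(td_features(synced.emg[s:e, 0])[5])
                   for s, e in lg.slide_windows(len(synced.emg), spec)]
        trace = lg.streaming_evaluate(
            lambda w: {"rms0": float(td_features(w[:, 0])[5])}, synced, spec)
        assert len(trace) == len(offline)
        np.testing.assert_allclose(trace["rms0"], offline, atol=1e-12)
        assert (trace["latency_s"] > 0).all()

    def test_sweep_grid(self, synced, labels):
        from lateralgait.baselines import BaselineSpec, fit_baseline
        from lateralgait.features import feature_columns

        def train_fn(train_df, spec, seed):
            X = train_df[feature_columns()].to_numpy()
            y = np.array([lg.PHASES.index(p) for p in train_df["phase"]])
            fitted = fit_baseline(BaselineSpec(kind="knn", seed=seed), X, y)
            from lateralgait.baselines import predict_baseline
            return lambda F: predict_baseline(fitted, F)[0]

        grid = lg.sweep_windows(synced, labels, [200, 250], [20, 40],
                                train_fn)
        assert len(grid) == 4
        assert "error" not in grid.columns or grid["error"].isna().all()
        # window-count formula governs every cell
        n = len(synced.emg)
        for _, row in grid.iterrows():
            L = int(row["length_ms"])
            S = int(row["increment_ms"])
            assert row["n_windows"] == (n - L) // S + 1
        # larger increment never increases the window count
        g = grid.set_index(["length_ms", "increment_ms"])["n_windows"]
        assert g[(200, 40)] <= g[(200, 20)]
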