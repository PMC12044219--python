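"""Architecture conformance, loss closed forms, attention-gate contracts,
and the training/prediction determinism of the dual-task model."""

import math

import numpy as np
import pytest

import lateralgait as lg
from lateralgait._nn import SEGate
from lateralgait.features import feature_columns
from lateralgait.twin import (ElderConfig, YoungerConfig, build_elder,
                              build_younger, count_parameters, load_model,
                              predict_dual, save_model, seam, train_twin)


def layer_counts(net):
    return dict(count_parameters(net).itertuples(index=False, name=None))


class TestArchitecture:
    def test_elder_parameter_counts(self):
        counts = layer_counts(build_elder())
        assert counts["conv1"] == 320
        assert counts["conv2"] == 18_496
        assert counts["fc1"] == 3_136
        assert counts["fc2"] == 1_040
        assert counts["output"] == 68

    def test_younger_parameter_counts(self):
        counts = layer_counts(build_younger())
        assert counts["hidden2"] == 252
        assert counts["hidden3"] == 78
        assert counts["output"] == 7

    def test_dense_count_closed_form(self):
        rng = np.random.default_rng(0)
        for m, n in [(3, 5), (48, 64), (16, 4)]:
            lay = lg.twin.Dense(m, n, rng)
            assert sum(p.size for p in lay.params()) == m * n + n

    def test_elder_output_shape_and_softmax(self):
        elder = build_elder()
        probs = elder.predict_proba(np.random.default_rng(1)
                                    .standard_normal((7, 48)))
        assert probs.shape == (7, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ElderConfig(classes=3)
        with pytest.raises(ValueError):
            ElderConfig(conv1_filters=30)  # not divisible by reduction
        with pytest.raises(ValueError):
            YoungerConfig(hidden=(10, 10, 10))

    def test_post_lstm_attention_variant_runs(self):
        elder = build_elder(ElderConfig(seam_placement="post_lstm"))
        probs = elder.predict_proba(np.zeros((3, 48)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestSeam:
    def test_zero_parameters_halve_channels(self):
        gate = SEGate(8, 8, 2, np.random.default_rng(0))
        for p in gate.params():
            p.v[...] = 0.0
        x = np.random.default_rng(1).standard_normal((4, 5, 8))
        np.testing.assert_allclose(seam(x, params=gate), 0.5 * x, atol=1e-12)

    def test_weights_strictly_in_unit_interval(self):
        gate = SEGate(8, 8, 2, np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((6, 5, 8))
        w = gate.weights(x)
        assert np.all(w > 0) and np.all(w < 1)
        # extreme inputs may saturate to the float boundary but never beyond
        w_big = gate.weights(x * 1e6)
        assert np.all(w_big >= 0) and np.all(w_big <= 1)

    def test_zero_maps_give_zero_output(self):
        out = seam(np.zeros((2, 4, 8)), seed=5)
        np.testing.assert_array_equal(out, 0.0)

    def test_channel_count_must_divide_by_four(self):
        with pytest.raises(ValueError):
            seam(np.zeros((1, 4, 6)))


class TestLosses:
    def test_cross_entropy_perfect_prediction(self):
        onehot = np.eye(4)
        assert lg.cross_entropy(onehot, onehot) == pytest.approx(0.0, abs=1e-9)

    def test_cross_entropy_uniform(self):
        probs = np.full((10, 4), 0.25)
        onehot = np.eye(4)[np.arange(10) % 4]
        assert lg.cross_entropy(probs, onehot) == pytest.approx(math.log(4))

    def test_cross_entropy_loop_oracle(self):
        rng = np.random.default_rng(8)
        raw = rng.random((20, 4))
        probs = raw / raw.sum(axis=1, keepdims=True)
        onehot = np.eye(4)[rng.integers(0, 4, 20)]
        expected = -sum(
            onehot[i, j] * math.log(probs[i, j])
            for i in range(20) for j in range(4)) / 20
        assert lg.cross_entropy(probs, onehot) == pytest.approx(
            expected, abs=1e-12)

    def test_cross_entropy_clamps_zero_probability(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        onehot = np.array([[1.0, 0.0, 0.0, 0.0]])
        val = lg.cross_entropy(probs, onehot)
        assert np.isfinite(val) and val == pytest.approx(-math.log(1e-12))

    def test_mse_examples_and_oracle(self):
        assert lg.mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert lg.mse_loss([3.0, 4.0], [0.0, 0.0]) == pytest.approx(12.5)
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(31), rng.standard_normal(31)
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) / 31
        assert lg.mse_loss(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            lg.mse_loss([1.0], [1.0, 2.0])


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_fit(self, features_df):
        df = features_df.iloc[::8]  # ~290 windows: enough to exercise paths
        feats = df[feature_columns()].to_numpy()
        phase = np.array([lg.PHASES.index(p) for p in df["phase"]])
        targets = {"theta_right": df["theta_right_deg"].to_numpy()}
        kw = dict(elder_cfg=ElderConfig(epochs=8, seed=1),
                  younger_cfg=YoungerConfig(epochs=8, seed=1))
        return feats, phase, targets, kw

    def test_loss_decreases_and_same_seed_identical(self, tiny_fit):
        feats, phase, targets, kw = tiny_fit
        m1 = train_twin(feats, phase, targets, **kw)
        m2 = train_twin(feats, phase, targets, **kw)
        assert m1.elder_losses[-1] < m1.elder_losses[0]
        assert m1.elder_losses == m2.elder_losses
        for pa, pb in zip(m1.elder.params(), m2.elder.params()):
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_predict_dual_contract(self, tiny_fit):
        feats, phase, targets, kw = tiny_fit
        model = train_twin(feats, phase, targets, **kw)
        probs, labels, angles = predict_dual(model, feats[:50])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(np.unique(labels)).issubset({0, 1, 2, 3})
        assert list(angles) == ["theta_right"]
        # batch prediction equals looped single-sample prediction
        for i in (0, 17, 49):
            p_i, l_i, a_i = predict_dual(model, feats[i:i + 1])
            np.testing.assert_allclose(p_i[0], probs[i], atol=1e-12)
            assert l_i[0] == labels[i]
            np.testing.assert_allclose(a_i["theta_right"][0],
                                       angles["theta_right"][i], atol=1e-12)

    def test_checkpoint_round_trip(self, tiny_fit, tmp_path):
        feats, phase, targets, kw = tiny_fit
        model = train_twin(feats, phase, targets, **kw)
        path = save_model(model, tmp_path / "model.npz")
        back = load_model(path)
        p0, l0, a0 = predict_dual(model, feats[:20])
        p1, l1, a1 = predict_dual(back, feats[:20])
        np.testing.assert_allclose(p0, p1, atol=1e-12)
        np.testing.assert_array_equal(l0, l1)
        np.testing.assert_allclose(a0["theta_right"], a1["theta_right"],
                                   atol=1e-12)

    def test_teacher_forcing_mode(self, tiny_fit):
        feats, phase, targets, kw = tiny_fit
        model = train_twin(feats, phase, targets, teacher_forcing=True, **kw)
        assert "theta_right" in model.youngers


class TestResultsSurface:
    def test_summary_reports_fit(self, trained_twin):
        text = trained_twin["results"].summary()
        assert "Twin Brother" in text
        assert "RMSE" in text and "R2" in text

    def test_angles_track_target_function_of_phase(self, trained_twin):
        # angles are a deterministic function of the gait cycle; the fitted
        # regressor must recover them on held-out windows far better than a
        # phase-mean predictor would
        res = trained_twin["results"]
        test_df = trained_twin["test_df"]
        ev = res.evaluate(
            trained_twin["test_X"], trained_twin["test_phase"],
            {"theta_left_deg": test_df["theta_left_deg"].to_numpy(),
             "theta_right_deg": test_df["theta_right_deg"].to_numpy()})
        assert ev["r2_theta_left_deg"] > 0.9
        assert ev["r2_theta_right_deg"] > 0.9
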