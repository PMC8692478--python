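"""Forecaster assembly: losses, fusion, training mechanics, serialization."""

from dataclasses import replace

import numpy as np
import pytest

from bgpredict.model import (BGPredictModel, ForecastBatch, ModelConfig,
                             build_model, event_weights, fuse, huber_loss,
                             weighted_sequence_loss)
from bgpredict.preprocess import WindowSet


class TestHuberLoss:
    def test_zero_error(self):
        assert huber_loss([0.2, 0.4], [0.2, 0.4], 0.5) == 0.0

    def test_quadratic_branch(self):
        # e = 0.3 <= delta: 0.5 * 0.3^2
        assert huber_loss([0.3], [0.0], 0.5) == pytest.approx(0.045)

    def test_linear_branch(self):
        # e = 1.0 > delta: 0.5 * (1.0 - 0.25)
        assert huber_loss([1.0], [0.0], 0.5) == pytest.approx(0.375)

    def test_continuity_at_delta(self):
        d = 0.5
        below = huber_loss([d - 1e-9], [0.0], d)
        above = huber_loss([d + 1e-9], [0.0], d)
        assert below == pytest.approx(above, abs=1e-8)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert huber_loss(a, b, 0.5) == pytest.approx(huber_loss(b, a, 0.5))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            huber_loss([1.0], [1.0, 2.0], 0.5)
        with pytest.raises(ValueError):
            huber_loss([1.0], [1.0], 0.0)


class TestEventWeights:
    @pytest.mark.parametrize("value,expected", [(60, 100.0), (69.99, 100.0),
                                                (70, 1.0), (179.99, 1.0),
                                                (180, 10.0), (200, 10.0)])
    def test_category_boundaries(self, value, expected):
        assert event_weights(np.array([value]))[0] == expected

    def test_weighted_loss_reduces_to_huber(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 1, (4, 6))
        yh = rng.uniform(0, 1, (4, 6))
        y_mgdl = rng.uniform(40, 300, (4, 6))
        cfg = ModelConfig(lambda_hypo=1.0, lambda_hyper=1.0)
        assert weighted_sequence_loss(y, yh, y_mgdl, cfg) == \
            pytest.approx(huber_loss(y, yh, cfg.delta))

    def test_mixed_batch_hand_weighted(self):
        # one hypo and one normo element with identical elementwise loss l
        cfg = ModelConfig()
        y = np.array([[0.2], [0.2]])
        yh = np.array([[0.3], [0.3]])
        y_mgdl = np.array([[60.0], [120.0]])
        l_elem = 0.5 * 0.1 ** 2
        expected = (100 * l_elem + 1 * l_elem) / 2
        assert weighted_sequence_loss(y, yh, y_mgdl, cfg) == \
            pytest.approx(expected, rel=1e-9)


class TestFuse:
    def test_selector(self):
        rng = np.random.default_rng(2)
        ys = [rng.normal(0, 1, (3, 4)) for _ in range(4)]
        W = np.zeros((4, 4))
        W[0] = 1.0
        np.testing.assert_allclose(fuse(ys, W), ys[0])

    def test_convex_identity(self):
        z = np.random.default_rng(3).normal(0, 1, (2, 5))
        W = np.full((4, 5), 0.25)
        np.testing.assert_allclose(fuse([z, z, z, z], W), z)

    def test_elementwise_product_over_horizon(self):
        W = np.zeros((4, 2))
        W[0] = [1.0, 2.0]
        ys = [np.array([[3.0, 4.0]]), np.zeros((1, 2)), np.zeros((1, 2)),
              np.zeros((1, 2))]
        np.testing.assert_allclose(fuse(ys, W), [[3.0, 8.0]])

    def test_linear_in_each_component(self):
        rng = np.random.default_rng(4)
        ys = [rng.normal(0, 1, (3, 4)) for _ in range(4)]
        W = rng.normal(0, 1, (4, 4))
        base = fuse(ys, W)
        ys2 = list(ys)
        ys2[2] = 2.0 * ys[2]
        np.testing.assert_allclose(fuse(ys2, W) - base, fuse(
            [np.zeros_like(ys[0])] * 2 + [ys[2]] + [np.zeros_like(ys[0])],
            W), atol=1e-12)

    def test_all_masked_rejected(self):
        with pytest.raises(RuntimeError):
            fuse([np.zeros((1, 2))] * 4, np.zeros((4, 2)), mask=(0, 0, 0, 0))


class TestBuildModel:
    def test_component_shapes_default_config(self, tiny_patient_windows):
        train_w, _, scaler = tiny_patient_windows
        cfg = ModelConfig()
        assert (cfg.p1, cfg.p2, cfg.p3, cfg.p4, cfg.f) == (36, 6, 36, 36, 6)
        m = build_model(cfg)
        # components consume (p, channels) views: (36x2),(6x1),(36x2),(36x2)
        from bgpredict.model import COMPONENT_CHANNELS
        assert COMPONENT_CHANNELS == (2, 1, 2, 2)
        assert m.fusion.value.shape == (4, 6)
        np.testing.assert_allclose(m.fusion.value, 0.25)

    def test_seeded_init_identical(self):
        cfg = ModelConfig(seed=9)
        a, b = build_model(cfg), build_model(cfg)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(component_mask=(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ModelConfig(delta=0.0)
        with pytest.raises(ValueError):
            ModelConfig(f=0)


class TestTraining:
    def test_masked_components_receive_no_updates(self, tiny_patient_windows,
                                                  tiny_config):
        train_w, _, scaler = tiny_patient_windows
        cfg = replace(tiny_config, component_mask=(0, 1, 0, 0), max_epochs=2)
        m = build_model(cfg, scaler=scaler)
        before = [[p.value.copy() for p in comp.params()]
                  for comp in m.components]
        m.train(train_w)
        for c in (0, 2, 3):
            for p, old in zip(m.components[c].params(), before[c]):
                np.testing.assert_array_equal(p.value, old)
        changed = any(not np.array_equal(p.value, old)
                      for p, old in zip(m.components[1].params(), before[1]))
        assert changed

    def test_lambda_choice_changes_trajectory(self, tiny_patient_windows,
                                              tiny_config):
        train_w, _, scaler = tiny_patient_windows
        cfg_w = replace(tiny_config, max_epochs=2)
        cfg_u = replace(cfg_w, lambda_hypo=1.0, lambda_hyper=1.0)
        mw = build_model(cfg_w, scaler=scaler).train(train_w)
        mu = build_model(cfg_u, scaler=scaler).train(train_w)
        diffs = [not np.allclose(a.value, b.value)
                 for a, b in zip(mw.params(), mu.params())]
        assert any(diffs)

    def test_epoch_bookkeeping(self, tiny_patient_windows, tiny_config):
        train_w, _, scaler = tiny_patient_windows
        cfg = replace(tiny_config, max_epochs=1, early_stop_patience=0)
        m = build_model(cfg, scaler=scaler).train(train_w)
        assert len(m.history["train_loss"]) == 1
        assert len(m.history["val_loss"]) == 1

    def test_training_reduces_loss(self, tiny_patient_windows, tiny_config):
        train_w, _, scaler = tiny_patient_windows
        m = build_model(replace(tiny_config, max_epochs=10), scaler=scaler)
        m.train(train_w)
        assert m.history["train_loss"][-1] < m.history["train_loss"][0]

    def test_empty_train_set_rejected(self, tiny_patient_windows, tiny_config):
        train_w, _, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler)
        with pytest.raises(ValueError):
            m.train(train_w.subset(slice(0, 0)))

    def test_deterministic_given_seed(self, tiny_patient_windows, tiny_config):
        train_w, _, scaler = tiny_patient_windows
        cfg = replace(tiny_config, max_epochs=2)
        a = build_model(cfg, scaler=scaler).train(train_w)
        b = build_model(cfg, scaler=scaler).train(train_w)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestPredict:
    def test_identical_windows_identical_predictions(self, tiny_patient_windows,
                                                     tiny_config):
        train_w, test_w, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler).train(train_w)
        two = test_w.subset(np.array([0, 0]))
        batch = m.predict(two)
        np.testing.assert_array_equal(batch.y_pred[0], batch.y_pred[1])

    def test_predictions_finite_and_descaled(self, tiny_patient_windows,
                                             tiny_config):
        train_w, test_w, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler).train(train_w)
        batch = m.predict(test_w)
        assert np.all(np.isfinite(batch.y_pred))
        assert 20 < np.mean(batch.y_pred) < 400  # mg/dL scale, not [0,1]

    def test_inference_ablation_changes_predictions(self, tiny_patient_windows,
                                                    tiny_config):
        train_w, test_w, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler).train(train_w)
        full = m.predict(test_w).y_pred
        masked = m.predict(test_w, component_mask=(1, 0, 1, 1)).y_pred
        assert not np.allclose(full, masked)
        assert m.config.component_mask == (1, 1, 1, 1)  # restored

    def test_no_leakage_past_anchor(self, tiny_patient_windows, tiny_config):
        """Replacing every input value after the anchor leaves predictions
        unchanged (windows end at the anchor by construction)."""
        train_w, test_w, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler).train(train_w)
        sub = test_w.subset(slice(0, 4))
        base = m.predict(sub).y_pred
        tampered = WindowSet(sub.x1.copy(), sub.x2.copy(), sub.x3.copy(),
                             sub.x4.copy(), np.full_like(sub.y, 99.0),
                             np.full_like(sub.y_mgdl, 500.0),
                             sub.anchor_bg_mgdl.copy(), sub.anchors.copy())
        np.testing.assert_array_equal(m.predict(tampered).y_pred, base)


class TestFusionReport:
    def test_untrained_reports_quarter_weights(self, tiny_config):
        m = build_model(tiny_config)
        rep = m.report_fusion_contributions()
        np.testing.assert_allclose(rep["mean_abs"], 0.25)
        assert rep["per_step_abs"].shape == (4, tiny_config.f)


class TestCheckpoint:
    def test_save_load_lossless(self, tiny_patient_windows, tiny_config,
                                tmp_path):
        train_w, test_w, scaler = tiny_patient_windows
        m = build_model(tiny_config, scaler=scaler).train(train_w)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = BGPredictModel.load(path)
        assert m2.config == m.config
        assert m2.scaler.ranges == m.scaler.ranges
        for pa, pb in zip(m.params(), m2.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        np.testing.assert_array_equal(m.predict(test_w).y_pred,
                                      m2.predict(test_w).y_pred)


class TestForecastBatch:
    def test_shape_and_finiteness_validation(self):
        with pytest.raises(ValueError):
            ForecastBatch(np.arange(2), np.zeros((2, 3)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ForecastBatch(np.arange(1), np.zeros((1, 2)),
                          np.full((1, 2), np.nan))
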