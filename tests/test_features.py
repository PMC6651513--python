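"""Softmax, CNN architecture, training determinism, overlays, fusion."""

import numpy as np
import pytest

from retfuse.features import (
    CNNConfig,
    FeatureVector,
    build_feature_cnn,
    fit_cnn,
    fuse_features,
    overlay_findings,
    prepare_input,
    recognize_modality,
    softmax,
)
from retfuse.oct_analysis import FindingMasks, LayerBoundarySet
from retfuse.scan_io import RetinalScan


class TestSoftmax:
    def test_symmetric_pair_gives_half(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_direct_formula_and_normalization(self):
        x = np.array([1.0, 2.0, 3.0])
        want = np.exp(x) / np.exp(x).sum()
        got = softmax(x)
        assert np.abs(got - want).max() < 1e-12
        assert abs(got.sum() - 1.0) < 1e-9

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, 10)
        assert np.allclose(softmax(x), softmax(x + 123.456), atol=1e-12)

    def test_large_inputs_stable(self):
        got = softmax([1000.0, 1000.0, 999.0])
        assert np.isfinite(got).all() and abs(got.sum() - 1) < 1e-9

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            softmax([])


class TestBuildFeatureCNN:
    def test_forward_default_geometry_yields_eight_features(self):
        model = build_feature_cnn(CNNConfig(), seed=0)
        x = np.random.default_rng(0).random((227, 227, 3)).astype(np.float32)
        feats = model.features(x)
        assert feats.shape == (1, 8)
        assert model.n_layers == 14

    def test_first_conv_parameter_count(self):
        # 9x9x3 kernels, 8 filters: 9*9*3*8 weights + 8 biases
        model = build_feature_cnn(CNNConfig(), seed=0)
        assert model.conv_parameter_counts()[0] == 9 * 9 * 3 * 8 + 8 == 1952

    def test_layer_description_matches_architecture(self):
        desc = CNNConfig().layer_descriptions()
        assert len(desc) == 14
        assert "zero-center" in desc[0]
        assert desc[-1].endswith("8 features")

    def test_wrong_input_shape_rejected(self):
        model = build_feature_cnn(CNNConfig(input_size=64), seed=0)
        with pytest.raises(ValueError):
            model.features(np.zeros((32, 32, 3), np.float32))


class TestTrainCNN:
    @staticmethod
    def _toy(n=24, size=32, seed=3):
        rng = np.random.default_rng(seed)
        x = np.repeat(rng.random((n, size, size, 1)).astype(np.float32) * 0.3 + 0.2, 3, axis=3)
        y = (np.arange(n) % 2)
        for i in np.flatnonzero(y):
            r, c = rng.integers(4, size - 6, 2)
            x[i, r:r + 3, c:c + 3, 0] = 1.0
            x[i, r:r + 3, c:c + 3, 1:] = 0.0
        return x, y

    def test_learns_separable_toy_task(self):
        x, y = self._toy()
        model = build_feature_cnn(CNNConfig(input_size=32), seed=1)
        log = fit_cnn(model, x, y, ["healthy", "me"], epochs=10, seed=1)
        acc = (model.predict_proba(x).argmax(1) == y).mean()
        assert acc >= 0.95
        assert all(r[2] >= 0 for r in log.rows)  # cross-entropy nonnegative

    def test_same_seed_identical_training(self):
        x, y = self._toy(n=8)
        logs = []
        models = []
        for _ in range(2):
            m = build_feature_cnn(CNNConfig(input_size=32), seed=5)
            logs.append(fit_cnn(m, x, y, ["healthy", "me"], epochs=2, seed=5))
            models.append(m)
        assert logs[0].rows == logs[1].rows
        s1, s2 = models[0].net.state_dict(), models[1].net.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_feature_extraction_deterministic_at_inference(self):
        x, y = self._toy(n=8)
        m = build_feature_cnn(CNNConfig(input_size=32), seed=2)
        fit_cnn(m, x, y, ["healthy", "me"], epochs=1, seed=2)
        f1 = m.features(x[:3])
        f2 = m.features(x[:3])
        assert np.array_equal(f1, f2)

    def test_single_class_rejected(self):
        x, _ = self._toy(n=6)
        m = build_feature_cnn(CNNConfig(input_size=32), seed=0)
        with pytest.raises(ValueError):
            fit_cnn(m, x, np.zeros(6, int), ["healthy", "me"], epochs=1)


class TestRecognizeModality:
    def test_untrained_model_rejected(self):
        m = build_feature_cnn(CNNConfig(input_size=32), seed=0)
        with pytest.raises(RuntimeError):
            recognize_modality(m, RetinalScan(np.zeros((64, 64))))

    def test_trained_on_toy_modalities_tags_scan(self):
        # modality stand-ins: dark-banded vs bright-circular images
        rng = np.random.default_rng(4)
        n = 16
        x = np.zeros((n, 32, 32, 3), np.float32)
        y = (np.arange(n) % 2)
        for i in range(n):
            if y[i]:
                x[i, :, :, :] = 0.55 + 0.1 * rng.random((32, 32, 1))
            else:
                x[i, 10:20, :, :] = 0.8
        m = build_feature_cnn(CNNConfig(input_size=32), seed=3)
        fit_cnn(m, x, y, ["oct", "fundus"], epochs=8, seed=3)
        scan = RetinalScan(np.full((100, 120), 0.6))  # gray is auto-replicated
        modality, prob = recognize_modality(m, scan)
        assert modality in ("oct", "fundus")
        assert scan.modality == modality
        assert 0.5 <= prob <= 1.0


class TestOverlayFindings:
    def test_empty_masks_replicate_scan(self):
        scan = RetinalScan(np.random.default_rng(0).random((20, 20)))
        out = overlay_findings(scan, FindingMasks())
        assert out.shape == (20, 20, 3)
        assert np.allclose(out[:, :, 0], scan.pixels)
        assert np.allclose(out[:, :, 1], scan.pixels)

    def test_fluid_pixels_recolored_exactly(self):
        scan = RetinalScan(np.full((10, 10), 0.5))
        fluid = np.zeros((10, 10), bool)
        fluid[2:4, 3:5] = True
        out = overlay_findings(scan, FindingMasks(fluid=fluid))
        assert np.allclose(out[fluid], (1.0, 0.0, 0.0))
        assert np.allclose(out[~fluid], 0.5)

    def test_original_untouched_and_idempotent(self):
        pixels = np.full((10, 10), 0.5)
        scan = RetinalScan(pixels.copy())
        fluid = np.eye(10, dtype=bool)
        out1 = overlay_findings(scan, FindingMasks(fluid=fluid))
        out2 = overlay_findings(scan, FindingMasks(fluid=fluid))
        assert np.array_equal(scan.pixels, pixels)
        assert np.array_equal(out1, out2)

    def test_boundary_curves_painted(self):
        scan = RetinalScan(np.full((20, 16), 0.3))
        curves = [np.full(16, 5.0), np.full(16, 12.0)]
        layers = LayerBoundarySet(curves, ilm_index=0, rpe_index=1)
        out = overlay_findings(scan, None, layers)
        assert np.allclose(out[5, :, :], (0.0, 0.0, 1.0))
        assert np.allclose(out[12, :, :], (0.0, 0.0, 1.0))

    def test_shape_mismatch_rejected(self):
        scan = RetinalScan(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            overlay_findings(scan, FindingMasks(fluid=np.zeros((5, 5), bool)))


class TestFuseFeatures:
    def test_order_is_oct_then_fundus(self):
        fv = fuse_features(np.arange(1, 9), np.arange(9, 17))
        assert np.array_equal(fv.values, np.arange(1, 17))
        assert fv.values.size == 16

    def test_order_matters(self):
        a, b = np.arange(8.0), np.arange(8.0, 16.0)
        assert not np.array_equal(fuse_features(a, b).values, fuse_features(b, a).values)

    def test_wrong_lengths_rejected(self):
        with pytest.raises(ValueError):
            fuse_features(np.zeros(7), np.zeros(8))

    def test_feature_vector_validates_length(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(15))


class TestPrepareInput:
    def test_gray_replicated_and_resized(self):
        out = prepare_input(np.random.default_rng(0).random((100, 80)), 32)
        assert out.shape == (32, 32, 3)
        assert np.array_equal(out[:, :, 0], out[:, :, 2])

    def test_values_stay_in_unit_interval(self):
        out = prepare_input(np.ones((50, 50)), 64)
        assert out.min() >= 0 and out.max() <= 1
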