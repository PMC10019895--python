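import math

import numpy as np
import pytest

from imcseg.compositing import CompositeImage
from imcseg.net import NetConfig, TrainingExample, UNet, bce_loss, binarize, predict, train
from imcseg.synthetic import generate_scene, make_training_set, scene_composite
from tests.conftest import tiny_scene_params


def bce_oracle(y, y_hat, eps=1e-7):
    """Plain-Python per-pixel summation of the cross-entropy formula."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    total = 0.0
    for yi, pi in zip(y, y_hat):
        pi = min(max(pi, eps), 1 - eps)
        total += yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
    return -total / len(y)


class TestBceLoss:
    def test_hand_evaluated_half(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_hand_evaluated_quarter(self):
        assert bce_loss(np.array([1.0]), np.array([0.25])) == pytest.approx(
            -math.log(0.25), abs=1e-12
        )

    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(y, y) < 1e-5

    def test_matches_summation_oracle(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(1, 6, size=2))
            y = (rng.random(shape) > 0.5).astype(float)
            y_hat = rng.random(shape)
            assert bce_loss(y, y_hat) == pytest.approx(bce_oracle(y, y_hat), abs=1e-9)

    def test_truth_is_minimum(self, rng):
        y = (rng.random(20) > 0.5).astype(float)
        at_truth = bce_loss(y, y)
        for _ in range(20):
            other = np.clip(y + rng.normal(0, 0.2, y.shape), 0, 1)
            assert at_truth <= bce_loss(y, other) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bce_loss(np.zeros(3), np.zeros(4))

    def test_nonbinary_target_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            bce_loss(np.array([0.5]), np.array([0.5]))


class TestBinarize:
    def test_threshold_split(self):
        np.testing.assert_array_equal(binarize(np.array([0.49, 0.51])), [0, 1])

    def test_tie_goes_to_foreground(self):
        np.testing.assert_array_equal(binarize(np.array([0.5])), [1])

    def test_zeros_stay_zeros(self):
        assert binarize(np.zeros((4, 4))).max() == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros(2), threshold=1.5)


class TestArchitecture:
    def test_output_matches_input_size_and_range(self):
        model = UNet(NetConfig(depth=2, base_filters=4, patch_size=32, seed=0))
        x = np.random.default_rng(0).random((2, 32, 32, 2)).astype(np.float32)
        prob = model.forward(x)
        assert prob.shape == (2, 32, 32)
        assert prob.min() >= 0 and prob.max() <= 1

    def test_minimal_depth_one_network(self):
        model = UNet(NetConfig(depth=1, base_filters=4, patch_size=16, seed=0))
        prob = model.forward(np.zeros((1, 16, 16, 2), dtype=np.float32))
        assert prob.shape == (1, 16, 16)

    def test_indivisible_input_rejected(self):
        model = UNet(NetConfig(depth=4, base_filters=4, patch_size=128, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 127, 127, 2), dtype=np.float32))

    def test_gradients_match_finite_differences(self):
        """Analytic backprop vs central differences on a tiny double-precision net."""
        cfg = NetConfig(depth=2, base_filters=3, patch_size=8, batch_size=2, seed=1)
        model = UNet(cfg)
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 2))
        y = (rng.random((2, 8, 8)) > 0.5).astype(np.float64)
        _, grads = model.loss_and_grads(x, y)
        for name in ["enc0_conv1_W", "bott_conv2_W", "dec1_up_W", "dec0_conv2_W", "out_W"]:
            flat = model.params[name].ravel()
            for i in rng.choice(flat.size, size=3, replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                lp = bce_loss(y, model.forward(x))
                flat[i] = orig - eps
                lm = bce_loss(y, model.forward(x))
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-3, abs=1e-9)

    def test_checkpoint_round_trip(self, tmp_path):
        model = UNet(NetConfig(depth=1, base_filters=4, patch_size=16, seed=3))
        x = np.random.default_rng(1).random((1, 16, 16, 2)).astype(np.float32)
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = UNet.load(path)
        assert loaded.config == model.config
        np.testing.assert_array_equal(loaded.forward(x), before)


def small_examples(n, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = rng.random((2, size, size)).astype(np.float32)
        y = (x[0] > 0.6).astype(np.float32)
        out.append(TrainingExample(x, y))
    return out


class TestTraining:
    def test_memorizes_single_repeated_example(self):
        cfg = NetConfig(depth=1, base_filters=8, patch_size=16, batch_size=8,
                        max_epochs=60, early_stop_patience=60,
                        validation_fraction=0.1, seed=0)
        examples = small_examples(1) * 16
        model = UNet(cfg)
        log = train(model, examples, cfg)
        assert log[-1]["train_loss"] < 0.05

    def test_validation_loss_improves(self):
        cfg = NetConfig(depth=2, base_filters=8, patch_size=32, batch_size=8,
                        max_epochs=10, early_stop_patience=10, seed=0)
        examples = make_training_set(
            [tiny_scene_params(seed=300 + i, height=64, width=64) for i in range(8)],
            patch_size=32,
        )
        model = UNet(cfg)
        log = train(model, examples, cfg)
        assert min(e["val_loss"] for e in log) < log[0]["val_loss"]

    def test_seeded_training_reproducible(self):
        cfg = NetConfig(depth=1, base_filters=4, patch_size=16, batch_size=4,
                        max_epochs=3, early_stop_patience=3, seed=42)
        examples = small_examples(8)
        logs = []
        for _ in range(2):
            model = UNet(cfg)
            logs.append(train(model, examples, cfg))
        assert logs[0] == logs[1]

    def test_too_few_examples_rejected(self):
        model = UNet(NetConfig(depth=1, base_filters=4, patch_size=16, seed=0))
        with pytest.raises(ValueError, match="at least 2"):
            train(model, small_examples(1), model.config)


class TestPredict:
    def test_output_shape_matches_arbitrary_input(self, tiny_model):
        for h, w in [(32, 32), (64, 96), (70, 45)]:
            rng = np.random.default_rng(h + w)
            comp = CompositeImage(rng.random((h, w)), rng.random((h, w)))
            prob = predict(tiny_model, comp)
            assert prob.shape == (h, w)
            assert prob.min() >= 0 and prob.max() <= 1

    def test_blank_input_no_seam_structure(self, tiny_model):
        """Identical (all-zero) tiles must produce identical outputs, so the
        merged map shows no invented structure across patch seams."""
        comp = CompositeImage(np.zeros((64, 64)), np.zeros((64, 64)))
        prob = predict(tiny_model, comp)
        quadrants = [prob[:32, :32], prob[:32, 32:], prob[32:, :32], prob[32:, 32:]]
        for q in quadrants[1:]:
            np.testing.assert_array_equal(q, quadrants[0])

    def test_foreground_probability_higher_inside_cells(self, tiny_model):
        scene = generate_scene(tiny_scene_params(seed=999))
        prob = predict(tiny_model, scene_composite(scene))
        inside = prob[scene.truth > 0].mean()
        outside = prob[scene.truth == 0].mean()
        assert inside - outside > 0.2


class TestAugmentation:
    def test_flip_rotate_augmentation_trains(self):
        cfg = NetConfig(depth=1, base_filters=4, patch_size=16, batch_size=4,
                        max_epochs=2, early_stop_patience=2, augment=True, seed=0)
        model = UNet(cfg)
        log = train(model, small_examples(8), cfg)
        assert len(log) == 2
        assert all(np.isfinite(e["train_loss"]) for e in log)
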