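"""Network contracts: shapes, parameter counts, augmentation, training."""

import numpy as np
import pytest

from airway2d._nn import UNet, softmax_cross_entropy
from airway2d.phantom import desk_spec, generate_phantom
from airway2d.segnet import (AugmentSpec, NetConfig, TrainConfig,
                             UNetSegmenter, augment_pair, build_model,
                             desk_net_config, load_model, predict,
                             save_model, train)


def analytic_param_count(in_ch, num_classes, base, depth, convs):
    """Independent count from the block definition: each conv is
    c_out*(c_in*9+1) weights plus 2*c_out batch-norm parameters."""
    total = 0

    def block(c_in, c_out):
        n = 0
        c = c_in
        for _ in range(convs):
            n += c_out * (c * 9 + 1) + 2 * c_out
            c = c_out
        return n

    c = in_ch
    for i in range(depth):
        total += block(c, base * 2**i)
        c = base * 2**i
    total += block(c, base * 2**depth)
    for i in reversed(range(depth)):
        total += block(base * 2**(i + 1) + base * 2**i, base * 2**i)
    total += num_classes * (base + 1)  # 1x1 head
    return total


class TestArchitecture:
    def test_variants_share_output_shape(self):
        x = np.random.default_rng(0).random((1, 2, 16, 16)).astype(np.float32)
        for variant in ("unet18", "unet36"):
            cfg = NetConfig(variant=variant, base_channels=4, depth_levels=2,
                            input_size_px=16)
            model = build_model(cfg, seed=0)
            out = model.forward(x, train=False)
            assert out.shape == (1, 4, 16, 16)
            assert np.isfinite(out).all()

    def test_deep_variant_has_more_parameters(self):
        shallow = build_model(NetConfig("unet18", base_channels=4,
                                        depth_levels=2, input_size_px=16))
        deep = build_model(NetConfig("unet36", base_channels=4,
                                     depth_levels=2, input_size_px=16))
        assert deep.n_parameters() > shallow.n_parameters()

    @pytest.mark.parametrize("convs", [2, 4])
    def test_parameter_count_matches_analytic_formula(self, convs):
        model = UNet(in_channels=2, num_classes=4, base_channels=4,
                     depth_levels=2, convs_per_block=convs)
        assert model.n_parameters() == analytic_param_count(2, 4, 4, 2, convs)

    def test_input_size_must_match_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(input_size_px=100, depth_levels=4)

    def test_argmax_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(1, 4, 8, 8))
        a = np.argmax(scores, axis=1)
        b = np.argmax(3.0 * scores + 7.0, axis=1)
        assert np.array_equal(a, b)


class TestGradient:
    def test_loss_gradient_matches_numeric(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 4, 3, 3))
        targets = rng.integers(0, 4, size=(2, 3, 3))
        loss, grad = softmax_cross_entropy(logits, targets)
        eps = 1e-6
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in logits.shape)
            lp = logits.copy()
            lp[i] += eps
            lm = logits.copy()
            lm[i] -= eps
            num = (softmax_cross_entropy(lp, targets)[0]
                   - softmax_cross_entropy(lm, targets)[0]) / (2 * eps)
            assert num == pytest.approx(grad[i], abs=1e-5)

    def test_network_directional_derivative(self, monkeypatch):
        """Central-difference check of the full backward pass along a
        random parameter direction (run in float64 so the finite
        difference is not drowned by rounding)."""
        import airway2d._nn as nn_mod
        monkeypatch.setattr(nn_mod, "DTYPE", np.float64)
        rng = np.random.default_rng(7)
        model = UNet(in_channels=2, num_classes=4, base_channels=2,
                     depth_levels=1, convs_per_block=2, seed=1)
        x = rng.random((2, 2, 8, 8))
        y = rng.integers(0, 4, size=(2, 8, 8))

        def loss_at():
            return softmax_cross_entropy(model.forward(x, train=True), y)

        loss, grad = loss_at()
        model.zero_grad()
        model.backward(grad)
        params = model.params()
        dirs = [rng.normal(size=p.value.shape) for p in params]
        analytic = sum(float((p.grad * d).sum())
                       for p, d in zip(params, dirs))
        eps = 1e-6
        for p, d in zip(params, dirs):
            p.value += eps * d
        lp, _ = loss_at()
        for p, d in zip(params, dirs):
            p.value -= 2 * eps * d
        lm, _ = loss_at()
        numeric = (lp - lm) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=1e-4)


class TestAugment:
    def test_identity_spec_is_noop(self, small_phantom):
        img, lab = augment_pair(small_phantom.image,
                                small_phantom.labels.grid, AugmentSpec(), 0)
        assert np.array_equal(img, small_phantom.image)
        assert np.array_equal(lab, small_phantom.labels.grid)

    def test_forced_flip_is_involution(self, small_phantom):
        spec = AugmentSpec(hflip_prob=1.0)
        i1, l1 = augment_pair(small_phantom.image,
                              small_phantom.labels.grid, spec, 1)
        i2, l2 = augment_pair(i1, l1, spec, 2)
        assert np.array_equal(i2, small_phantom.image)
        assert np.array_equal(l2, small_phantom.labels.grid)

    def test_rotation_preserves_label_alphabet(self, small_phantom):
        spec = AugmentSpec(rotation_max_deg=10.0)
        _, lab = augment_pair(small_phantom.image,
                              small_phantom.labels.grid, spec, 3)
        assert set(np.unique(lab)) <= {0, 1, 2, 3}

    def test_full_recipe_preserves_shapes_and_labels(self, small_phantom):
        from airway2d.segnet import reference_augmentation
        img, lab = augment_pair(small_phantom.image,
                                small_phantom.labels.grid,
                                reference_augmentation(), 4)
        assert img.shape == small_phantom.image.shape
        assert lab.shape == small_phantom.labels.grid.shape
        assert set(np.unique(lab)) <= {0, 1, 2, 3}

    def test_deterministic_per_seed(self, small_phantom):
        spec = AugmentSpec(resize_range=(0.9, 1.1), rotation_max_deg=5)
        a = augment_pair(small_phantom.image, small_phantom.labels.grid,
                         spec, 9)
        b = augment_pair(small_phantom.image, small_phantom.labels.grid,
                         spec, 9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 5), dtype=int),
                         AugmentSpec(), 0)


class TestTraining:
    def test_zero_learning_rate_is_null_update(self, small_phantom):
        model = build_model(desk_net_config(), seed=0)
        before = [p.value.copy() for p in model.params()]
        model, trace = train(model, [small_phantom],
                             TrainConfig(learning_rate=0.0, batch_size=1,
                                         epochs=3), input_size=64)
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)
        assert np.allclose(trace, trace[0])

    def test_loss_decreases_in_trend(self, small_phantom):
        model = build_model(desk_net_config(), seed=0)
        _, trace = train(model, [small_phantom],
                         TrainConfig(learning_rate=1e-3, batch_size=1,
                                     epochs=30), input_size=64)
        assert trace[-1] < trace[0]
        ma = np.convolve(trace, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(ma) < 0.02)  # monotone up to noise

    def test_empty_dataset_rejected(self):
        model = build_model(desk_net_config())
        with pytest.raises(ValueError, match="at least one"):
            train(model, [], TrainConfig(epochs=1), input_size=64)

    def test_single_class_labels_rejected(self):
        model = build_model(desk_net_config())
        pair = (np.zeros((64, 64)), np.zeros((64, 64), dtype=int))
        with pytest.raises(ValueError, match="degenerate"):
            train(model, [pair], TrainConfig(epochs=1), input_size=64)

    def test_training_is_reproducible(self, small_phantom):
        traces = []
        for _ in range(2):
            model = build_model(desk_net_config(), seed=5)
            _, trace = train(model, [small_phantom],
                             TrainConfig(learning_rate=1e-3, batch_size=1,
                                         epochs=5, seed=5), input_size=64)
            traces.append(trace)
        assert traces[0] == traces[1]


class TestPredictAndPersistence:
    def test_prediction_contract(self, small_phantom):
        model = build_model(desk_net_config(), seed=0)
        lm = predict(model, small_phantom.image, input_size=64)
        assert lm.grid.shape == small_phantom.image.shape
        assert set(np.unique(lm.grid)) <= {0, 1, 2, 3}

    def test_all_background_image_no_crash(self):
        model = build_model(desk_net_config(), seed=0)
        lm = predict(model, np.full((96, 96), 0.7), input_size=64)
        assert lm.grid.shape == (96, 96)

    def test_checkpoint_roundtrip(self, tmp_path, small_phantom):
        model = build_model(desk_net_config(), seed=2)
        _, _ = train(model, [small_phantom],
                     TrainConfig(learning_rate=1e-3, batch_size=1, epochs=2),
                     input_size=64)
        path = tmp_path / "m.npz"
        save_model(model, path, input_size=64)
        loaded, meta = load_model(path)
        assert meta["input_size"] == 64
        a = predict(model, small_phantom.image, input_size=64).grid
        b = predict(loaded, small_phantom.image, input_size=64).grid
        assert np.array_equal(a, b)


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        est = UNetSegmenter.desk(epochs=2, seed=3)
        params = est.get_params()
        assert params["epochs"] == 2
        c = clone(est)
        assert c.get_params() == params

    def test_fit_predict_smoke(self, small_phantom):
        est = UNetSegmenter.desk(epochs=3, seed=0)
        est.fit_samples([small_phantom])
        assert len(est.loss_trace_) == 3
        pred = est.predict([small_phantom.image])[0]
        assert pred.shape == small_phantom.image.shape

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            UNetSegmenter.desk().predict([np.zeros((64, 64))])
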