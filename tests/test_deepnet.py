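"""NumPy deep-learning components: ResNet-50 parameter accounting, UNet
forward/backward correctness, training loop behaviour, augmentation."""

import numpy as np
import pytest

from cinescar.metrics import ClassWeights
from cinescar.nn import (
    TrainConfig,
    UNetConfig,
    augment,
    build_resnet50_classifier,
    build_unet,
    learning_rate_at_epoch,
    train_model,
)
from cinescar.nn.train import one_hot_masks, weighted_ce_loss_grad, weighted_dice_loss_grad


class TestResNet50Counts:
    def test_32_channel_totals(self):
        spec = build_resnet50_classifier(32)
        assert spec.total_params == 23_680_705
        assert spec.trainable_params == 23_627_585

    def test_3_channel_matches_canonical_reference(self):
        # canonical headless topology totals 23,587,712 (conv biases included,
        # BN moving stats counted); the single-unit head adds 2048 + 1
        spec = build_resnet50_classifier(3)
        assert spec.total_params == 23_587_712 + 2049

    def test_input_channels_affect_only_first_conv(self):
        for c in (1, 8, 32, 64):
            delta = build_resnet50_classifier(c).total_params - build_resnet50_classifier(3).total_params
            assert delta == (c - 3) * 7 * 7 * 64

    def test_layer_count_is_fifty_plus_bns(self):
        spec = build_resnet50_classifier(32)
        convs = [l for l in spec.layers if ".conv" in l.name or l.name == "stem.conv"]
        # 1 stem + 3*(3,4,6,3) bottleneck convs + 4 shortcut convs = 53
        assert len(convs) == 53

    def test_invalid_channels_rejected(self):
        with pytest.raises(ValueError):
            build_resnet50_classifier(0)


def unet_param_count_by_hand(cfg: UNetConfig) -> tuple:
    """Independent layer-by-layer sum of the declared UNet topology."""

    def conv(cin, cout, k=3):
        return k * k * cin * cout + cout

    def bn_train(ch):
        return 2 * ch

    def bn_total(ch):
        return 4 * ch

    f = cfg.base_filters
    trainable = total = 0

    def block(cin, cout):
        nonlocal trainable, total
        trainable += conv(cin, cout) + bn_train(cout)
        total += conv(cin, cout) + bn_total(cout)

    cin = cfg.input_channels
    for d in range(cfg.depth):
        cout = f * 2**d
        block(cin, cout)
        block(cout, cout)
        cin = cout
    cb = f * 2**cfg.depth
    block(cin, cb)
    block(cb, cb)
    cin = cb
    for d in reversed(range(cfg.depth)):
        cout = f * 2**d
        block(cin, cout)  # up-sampling conv
        block(cout * 2, cout)
        block(cout, cout)
        cin = cout
    trainable += conv(cin, cfg.output_channels, 1)
    total += conv(cin, cfg.output_channels, 1)
    return total, trainable


class TestUNet:
    def test_forward_shape_contract(self):
        model, _, _ = build_unet(UNetConfig())
        x = np.random.default_rng(0).normal(0, 1, (2, 32, 64, 64))
        out = model.forward(x)
        assert out.shape == (2, 4, 64, 64)

    def test_output_channels_sum_to_one(self):
        model, _, _ = build_unet(UNetConfig())
        x = np.random.default_rng(1).normal(0, 1, (1, 32, 64, 64))
        out = model.forward(x)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_hand_derivation(self):
        cfg = UNetConfig()
        _, total, trainable = build_unet(cfg)
        assert (total, trainable) == unet_param_count_by_hand(cfg)

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(image_size=60, depth=3)

    def test_gradients_match_finite_differences(self):
        """Median-of-parameters check: max-pooling over tied ReLU zeros has
        only a subgradient there, so a small fraction of parameters may
        legitimately disagree with the symmetric difference quotient."""
        cfg = UNetConfig(input_channels=2, base_filters=2, depth=2, image_size=8, dropout_rate=0.0)
        model, _, _ = build_unet(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2, 2, 8, 8))
        y = one_hot_masks(rng.integers(0, 4, (2, 8, 8)))

        def loss_value():
            return weighted_dice_loss_grad(y, model.forward(x))[0]

        model.zero_grad()
        _, grad = weighted_dice_loss_grad(y, model.forward(x))
        model.backward(grad)
        rel_errors = []
        for param in [p for p in model.parameters() if p.trainable][::5]:
            idx = np.unravel_index(np.argmax(np.abs(param.grad)), param.value.shape)
            eps, orig = 1e-6, param.value[idx]
            param.value[idx] = orig + eps
            up = loss_value()
            param.value[idx] = orig - eps
            down = loss_value()
            param.value[idx] = orig
            numeric = (up - down) / (2 * eps)
            denom = max(abs(numeric) + abs(param.grad[idx]), 1e-12)
            rel_errors.append(abs(numeric - param.grad[idx]) / denom)
        assert len(rel_errors) >= 5
        assert np.median(rel_errors) < 1e-5

    def test_layer_gradients_exact(self, rng):
        """Conv, batch-norm (train mode) and dense backward passes agree with
        finite differences away from any non-smooth point."""
        from cinescar.nn.layers import BatchNorm2d, Conv2D, Dense

        x_conv = rng.normal(0, 1, (2, 3, 6, 6))
        conv = Conv2D(3, 4, 3, rng=np.random.default_rng(1))
        bn = BatchNorm2d(4)
        dense = Dense(8, 2, rng=np.random.default_rng(2))
        w = rng.normal(0, 1, (2, 4, 6, 6))  # random linear functional as loss

        def forward_loss():
            return float(np.sum(bn.forward(conv.forward(x_conv), train=True) * w))

        base = forward_loss()
        for layer in (conv, bn):
            for p in layer.params():
                if not p.trainable:
                    continue
                p.grad = np.zeros_like(p.value)
        conv.backward(bn.backward(w))
        for layer in (conv, bn):
            for p in layer.params():
                if not p.trainable:
                    continue
                idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.value.shape)
                eps, orig = 1e-6, p.value[idx]
                p.value[idx] = orig + eps
                numeric = (forward_loss() - base) / eps
                p.value[idx] = orig
                assert numeric == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-7), p.name
        x_dense = rng.normal(0, 1, (5, 8))
        wd = rng.normal(0, 1, (5, 2))
        base_d = float(np.sum(dense.forward(x_dense) * wd))
        dense.backward(wd)
        idx = np.unravel_index(np.argmax(np.abs(dense.w.grad)), dense.w.value.shape)
        eps, orig = 1e-6, dense.w.value[idx]
        dense.w.value[idx] = orig + eps
        numeric = (float(np.sum(dense.forward(x_dense) * wd)) - base_d) / eps
        dense.w.value[idx] = orig
        assert numeric == pytest.approx(dense.w.grad[idx], rel=1e-5)


class TestLosses:
    def test_dice_grad_matches_finite_difference(self, rng):
        y = one_hot_masks(rng.integers(0, 4, (1, 6, 6)))
        p = rng.uniform(0.05, 0.95, (1, 4, 6, 6))
        loss, grad = weighted_dice_loss_grad(y, p)
        eps = 1e-7
        for _ in range(5):
            i = tuple(rng.integers(0, s) for s in p.shape)
            p2 = p.copy()
            p2[i] += eps
            numeric = (weighted_dice_loss_grad(y, p2)[0] - loss) / eps
            assert numeric == pytest.approx(grad[i], rel=1e-4, abs=1e-9)

    def test_ce_grad_matches_finite_difference(self, rng):
        y = rng.integers(0, 2, 10)
        p = rng.uniform(0.05, 0.95, 10)
        w = ClassWeights((0.7, 1.6), (1, 1), 2, 2)
        loss, grad = weighted_ce_loss_grad(y, p, w)
        eps = 1e-8
        for i in range(10):
            p2 = p.copy()
            p2[i] += eps
            numeric = (weighted_ce_loss_grad(y, p2, w)[0] - loss) / eps
            assert numeric == pytest.approx(grad[i], rel=1e-5)


class TestTraining:
    def phantom_batch(self, n=4):
        """Cine stacks with aligned LGE-derived masks (the pipeline's actual
        segmentation ground truth — it carries the scar label)."""
        from cinescar.phantom import PhantomConfig, generate_cine_phantom, generate_lge_from_phantom
        from cinescar.transforms import AffineParams

        xs, ys = [], []
        for i in range(n):
            cfg = PhantomConfig(
                scar_present=bool(i % 2), seed=300 + i, lge_misalignment=AffineParams.identity()
            )
            cine, masks = generate_cine_phantom(cfg)
            lge = generate_lge_from_phantom(cine, masks, cfg)
            xs.append(np.stack(cine.frames))
            ys.append(lge.true_mask)
        return np.array(xs), np.array(ys)

    def test_lr_schedule_worked_example(self):
        cfg = TrainConfig(learning_rate=1e-3)
        assert learning_rate_at_epoch(cfg, 3) == pytest.approx(1e-3)
        assert learning_rate_at_epoch(cfg, 7) == pytest.approx(1e-3 * np.exp(-0.2))

    def test_loss_decreases(self):
        x, y = self.phantom_batch()
        model, _, _ = build_unet(UNetConfig())
        cfg = TrainConfig(max_epochs=8, patience=8, batch_size=4, seed=0)
        history, _ = train_model(model, (x, y), loss="dice", cfg=cfg)
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_seeded_runs_reproduce_loss_curve(self):
        x, y = self.phantom_batch(2)
        curves = []
        for _ in range(2):
            model, _, _ = build_unet(UNetConfig(seed=1))
            cfg = TrainConfig(max_epochs=3, patience=3, batch_size=2, seed=5)
            history, _ = train_model(model, (x, y), loss="dice", cfg=cfg)
            curves.append(history.train_loss.to_numpy())
        assert np.array_equal(curves[0], curves[1])

    def test_overfit_small_phantom_set(self):
        """Capacity sanity: the scaled UNet memorises 4 studies (loss < 0.2)."""
        x, y = self.phantom_batch(4)
        model, _, _ = build_unet(UNetConfig())
        cfg = TrainConfig(
            learning_rate=1e-2,
            decay_after_epochs=60,  # constant rate over this short run
            max_epochs=60,
            patience=60,
            batch_size=4,
            seed=0,
        )
        history, _ = train_model(model, (x, y), loss="dice", cfg=cfg)
        assert history.attrs["best_loss"] < 0.2

    def test_wce_training_with_class_weights(self, rng):
        from cinescar.metrics import compute_class_weights
        from cinescar.nn.layers import Dense, GlobalAvgPool, Sigmoid

        class TinyClassifier:
            def __init__(self):
                self.gap = GlobalAvgPool()
                self.fc = Dense(3, 1, rng=np.random.default_rng(0))
                self.act = Sigmoid()

            def parameters(self):
                return self.fc.params()

            def count_parameters(self):
                return 4, 4

            def get_weights(self):
                return [p.value.copy() for p in self.parameters()]

            def set_weights(self, ws):
                for p, w in zip(self.parameters(), ws):
                    p.value = w.copy()

            def zero_grad(self):
                for p in self.parameters():
                    p.grad = np.zeros_like(p.value)

            def forward(self, x, train=False):
                return self.act.forward(self.fc.forward(self.gap.forward(x)))

            def backward(self, grad):
                return self.gap.backward(self.fc.backward(self.act.backward(grad)))

        y = np.repeat([0, 1], [30, 10])
        x = np.zeros((40, 3, 4, 4))
        x[y == 1] += 1.0
        x += rng.normal(0, 0.2, x.shape)
        weights = compute_class_weights(np.bincount(y), 2)
        model = TinyClassifier()
        cfg = TrainConfig(max_epochs=60, patience=60, batch_size=8, seed=0, learning_rate=0.05)
        history, _ = train_model(model, (x, y), loss="wce", cfg=cfg, loss_weights=weights)
        pred = model.forward(x).ravel() > 0.5
        assert np.mean(pred == y) >= 0.9

    def test_empty_dataset_rejected(self):
        model, _, _ = build_unet(UNetConfig())
        with pytest.raises(ValueError):
            train_model(model, (np.zeros((0, 32, 64, 64)), np.zeros((0, 64, 64))), "dice")


class TestAugment:
    def test_intensity_bounds_and_labels(self, rng):
        images = rng.normal(0.5, 0.3, (3, 2, 16, 16))
        masks = rng.integers(0, 4, (3, 16, 16))
        out_i, out_m = augment(images, masks, rotation_deg=60.0, rng=np.random.default_rng(0))
        assert out_i.min() >= 0.0
        assert out_i.max() <= 1.0
        assert set(np.unique(out_m)).issubset({0, 1, 2, 3})

    def test_zero_rotation_only_normalises(self, rng):
        images = rng.uniform(0, 1, (1, 1, 12, 12))
        out = augment(images, rotation_deg=0.0, rng=np.random.default_rng(0))
        lo, hi = np.percentile(images[0], (1, 99))
        expected = np.clip((images[0] - lo) / (hi - lo), 0, 1)
        assert np.allclose(out[0], expected, atol=1e-9)
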