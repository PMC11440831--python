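"""U-net architecture, dice loss, gradients, training loop, cross-validation."""

import numpy as np
import pytest
from dataclasses import replace

import bodycomp as bc
from bodycomp.nn import (Adam, TrainConfig, TrainingDivergedError, UNetConfig,
                         build_unet, dice_loss, dice_loss_and_grad, hard_dice,
                         one_hot, run_5fold_cv, train_model)
from bodycomp.nn.unet import UNetConfigError


class TestArchitecture:
    def test_filter_progression_doubles_per_level(self):
        cfg = UNetConfig(depth=4, base_filters=64)
        assert cfg.encoder_filters == [64, 128, 256, 512]
        assert cfg.bottleneck_filters == 1024
        net = build_unet(cfg)
        assert net.params["enc0_1_W"].shape == (3, 3, 1, 64)
        assert net.params["bot_1_W"].shape == (3, 3, 512, 1024)
        assert net.params["dec3_1_W"].shape == (3, 3, 1024 + 512, 512)

    def test_full_scale_l3_input_keeps_spatial_shape(self):
        # depth-4 architecture at the clinical L3 input size (1088 x 512);
        # a narrow filter bank keeps this unit test in memory
        net = build_unet(UNetConfig(depth=4, base_filters=4, n_classes=2, seed=0))
        x = np.zeros((1, 1088, 512, 1), dtype=np.float32)
        logits = net.forward(x)
        assert logits.shape == (1, 1088, 512, 2)

    def test_probabilities_sum_to_one(self):
        net = build_unet(UNetConfig.body_desk(seed=3))
        x = np.random.default_rng(0).random((2, 32, 32, 1), dtype=np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 32, 32, 5)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_indivisible_input_rejected(self):
        net = build_unet(UNetConfig(depth=3, base_filters=4))
        with pytest.raises(UNetConfigError, match="divisible"):
            net.forward(np.zeros((1, 30, 32, 1), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path):
        net = build_unet(UNetConfig.body_desk(seed=5))
        x = np.random.default_rng(1).random((1, 16, 16, 1), dtype=np.float32)
        ref = net.forward(x)
        net.save(tmp_path / "m.npz")
        back = bc.UNet.load(tmp_path / "m.npz")
        assert back.config == net.config
        assert np.array_equal(back.forward(x), ref)


class TestDiceLoss:
    def test_perfect_binary_agreement_is_zero(self):
        m = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(float)
        assert dice_loss(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_masks_approach_one(self):
        a = np.zeros((64, 64)); a[:32] = 1
        b = np.zeros((64, 64)); b[32:] = 1
        assert dice_loss(a, b) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_half_probability(self):
        target = np.zeros((64, 64)); target[:, :32] = 1
        pred = np.full((64, 64), 0.5)
        assert dice_loss(pred, target) == pytest.approx(0.5, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_empty_maps_give_zero_by_smoothing(self):
        assert dice_loss(np.zeros((8, 8)), np.zeros((8, 8))) == 0.0

    def test_loss_decreases_with_overlap_on_enumerated_masks(self):
        """Over all 4-pixel binary mask pairs, the loss is in [0, 1] and,
        at fixed |A| and |B|, strictly decreases as |A n B| grows."""
        from itertools import product
        table = {}
        for bits_a in product([0, 1], repeat=4):
            for bits_b in product([0, 1], repeat=4):
                a = np.array(bits_a, dtype=float)
                b = np.array(bits_b, dtype=float)
                loss = dice_loss(a, b)
                assert 0.0 <= loss <= 1.0
                key = (int(a.sum()), int(b.sum()))
                inter = int((a * b).sum())
                table.setdefault(key, {})[inter] = loss
        for key, by_inter in table.items():
            inters = sorted(by_inter)
            losses = [by_inter[i] for i in inters]
            assert all(x > y for x, y in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        net = build_unet(UNetConfig(depth=2, base_filters=3, n_classes=3, seed=0))
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        net.params["out_W"] = rng.normal(0, 0.3, net.params["out_W"].shape)
        x = rng.random((2, 8, 8, 1)).astype(np.float64)
        y = rng.integers(0, 3, (2, 8, 8))
        g = one_hot(y, 3).astype(np.float64)
        fg = np.arange(1, 3)
        logits, cache = net.forward(x, want_cache=True)
        _, dl = dice_loss_and_grad(logits, g, fg)
        grads = net.backward(dl, cache)
        direction = {k: rng.normal(size=v.shape) for k, v in net.params.items()}
        analytic = sum(float((grads[k] * direction[k]).sum()) for k in grads)
        eps = 1e-6
        p0 = {k: v.copy() for k, v in net.params.items()}
        for k in net.params:
            net.params[k] = p0[k] + eps * direction[k]
        l1, _ = dice_loss_and_grad(net.forward(x), g, fg)
        for k in net.params:
            net.params[k] = p0[k] - eps * direction[k]
        l2, _ = dice_loss_and_grad(net.forward(x), g, fg)
        fd = (l1 - l2) / (2 * eps)
        assert analytic == pytest.approx(fd, rel=1e-3)


class TestLayersAgainstReferences:
    def test_conv3x3_matches_scipy_correlate(self):
        from scipy.signal import correlate2d
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 6, 6, 3))
        w = rng.normal(size=(3, 3, 3, 4))
        b = rng.normal(size=4)
        from bodycomp.nn.layers import conv3x3_forward
        out = conv3x3_forward(x, w, b)
        for n in range(2):
            for k in range(4):
                ref = sum(correlate2d(x[n, :, :, c], w[:, :, c, k], mode="same")
                          for c in range(3)) + b[k]
                assert np.allclose(out[n, :, :, k], ref, atol=1e-12)

    def test_pool_and_upsample_adjointness(self):
        from bodycomp.nn.layers import (maxpool2_forward, maxpool2_backward,
                                        upsample2_forward, upsample2_backward)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4, 4, 3))
        out, idx = maxpool2_forward(x)
        assert np.allclose(out, x.reshape(2, 2, 2, 2, 2, 3).max(axis=(2, 4)))
        dout = rng.normal(size=out.shape)
        dx = maxpool2_backward(dout, idx, x.shape)
        assert np.isclose(dx.sum(), dout.sum())
        xu = rng.normal(size=(1, 3, 3, 2))
        yu = rng.normal(size=(1, 6, 6, 2))
        assert np.isclose((upsample2_forward(xu) * yu).sum(),
                          (xu * upsample2_backward(yu)).sum())


def _blob_task(n=1, size=32, seed=0):
    """Tiny synthetic task: segment a bright disc on a dark background."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for _ in range(n):
        cy, cx = rng.uniform(10, size - 10, 2)
        r = rng.uniform(5, 9)
        yy, xx = np.mgrid[:size, :size]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img = rng.normal(0.2, 0.05, (size, size))
        img[mask] += 0.6
        xs.append(img)
        ys.append(mask.astype(np.int64))
    return np.stack(xs).astype(np.float32)[..., None], np.stack(ys)


class TestTraining:
    def test_overfits_single_easy_sample(self):
        x, y = _blob_task(n=1, seed=2)
        net = build_unet(UNetConfig(depth=2, base_filters=8, n_classes=2, seed=0))
        cfg = TrainConfig(max_epochs=50, learning_rate=3e-3, patience=1000, seed=0)
        net, history = train_model(net, (x, y), (x, y), cfg)
        assert max(h["val_dice"] for h in history) >= 0.95

    def test_early_stopping_after_patience_without_improvement(self):
        x, y = _blob_task(n=2, seed=3)
        # a huge min_delta means no epoch ever counts as an improvement
        cfg = TrainConfig(max_epochs=50, patience=3, min_delta=10.0, seed=0)
        net = build_unet(UNetConfig(depth=2, base_filters=2, n_classes=2, seed=0))
        _, history = train_model(net, (x, y), (x, y), cfg)
        assert len(history) == cfg.patience + 1

    def test_same_seed_reproduces_history(self):
        x, y = _blob_task(n=4, seed=4)
        cfg = TrainConfig(max_epochs=3, seed=11)
        h = []
        for _ in range(2):
            net = build_unet(UNetConfig(depth=2, base_filters=4, n_classes=2, seed=7))
            _, hist = train_model(net, (x[:3], y[:3]), (x[3:], y[3:]), cfg)
            h.append(hist)
        assert h[0] == h[1]

    def test_checkpoint_is_best_validation_dice_epoch(self):
        x, y = _blob_task(n=4, seed=5)
        cfg = TrainConfig(max_epochs=8, learning_rate=3e-3, patience=1000, seed=0)
        net = build_unet(UNetConfig(depth=2, base_filters=4, n_classes=2, seed=1))
        net, history = train_model(net, (x[:3], y[:3]), (x[3:], y[3:]), cfg)
        best = max(h["val_dice"] for h in history)
        pred = net.forward(x[3:]).argmax(axis=-1)
        rescored = np.mean([hard_dice(pred[i], y[3:][i], [1]) for i in range(1)])
        assert rescored == pytest.approx(best, abs=1e-12)

    def test_non_finite_input_aborts_with_diagnostic(self):
        x, y = _blob_task(n=2, seed=6)
        x[0, 0, 0, 0] = np.nan
        net = build_unet(UNetConfig(depth=2, base_filters=2, n_classes=2, seed=0))
        with pytest.raises(TrainingDivergedError):
            train_model(net, (x, y), (x, y), TrainConfig(max_epochs=2, seed=0))

    def test_empty_set_rejected(self):
        x, y = _blob_task(n=2, seed=7)
        net = build_unet(UNetConfig(depth=2, base_filters=2, n_classes=2, seed=0))
        with pytest.raises(ValueError):
            train_model(net, (x[:0], y[:0]), (x, y), TrainConfig(seed=0))

    def test_learns_phantom_segmentation_smoke(self):
        """A reduced net (depth 3, base 8) on 20 noise-free phantom slices
        learns the tissue layout to val DICE >= 0.8 within 15 short epochs —
        the task is learnable end to end at unit-test scale."""
        specs = [bc.PhantomSpec.desk(seed=400 + i, noise_sd_hu=0.0) for i in range(24)]
        data = [bc.generate_l3_slice(s) for s in specs]
        x = bc.hu_to_unit(np.stack([hu for hu, _ in data]))[..., None]
        y = np.stack([lm.labels for _, lm in data]).astype(np.int64)
        net = build_unet(UNetConfig(depth=3, base_filters=8, n_classes=5, seed=2))
        cfg = TrainConfig(max_epochs=15, learning_rate=2e-3, batch_size=1,
                          patience=1000, seed=2)
        net, history = train_model(net, (x[:20], y[:20]), (x[20:], y[20:]), cfg)
        assert max(h["val_dice"] for h in history) >= 0.8


class TestCrossValidation:
    def test_partition_properties_and_aggregation(self):
        x, y = _blob_task(n=10, seed=8)
        cfg = TrainConfig(max_epochs=1, seed=0)
        res = run_5fold_cv(x, y, UNetConfig(depth=2, base_filters=2, n_classes=2),
                           cfg, n_folds=5, seed=1)
        folds = [r["val_indices"] for r in res["folds"]]
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(folds[i]) & set(folds[j])
        dices = [r["val_dice"] for r in res["folds"]]
        assert res["mean"]["val_dice"] == pytest.approx(np.mean(dices))

    def test_too_few_samples_rejected(self):
        x, y = _blob_task(n=3, seed=9)
        with pytest.raises(ValueError):
            run_5fold_cv(x, y, UNetConfig(depth=2, base_filters=2, n_classes=2),
                         TrainConfig(max_epochs=1), n_folds=5)

    def test_metric_fn_hook_reported_per_fold(self):
        x, y = _blob_task(n=5, seed=10)
        res = run_5fold_cv(x, y, UNetConfig(depth=2, base_filters=2, n_classes=2),
                           TrainConfig(max_epochs=1), n_folds=5,
                           metric_fn=lambda m, xv, yv: {"n_val": float(len(xv))})
        assert all(r["n_val"] == 1.0 for r in res["folds"])


def test_adam_moves_parameters_toward_gradient_descent():
    params = {"w": np.array([1.0, -1.0])}
    opt = Adam(params, lr=0.1)
    for _ in range(5):
        opt.step(params, {"w": np.array([1.0, -1.0])})
    assert params["w"][0] < 1.0 and params["w"][1] > -1.0
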