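"""SE-RCNet architecture, SE recalibration, and training behavior."""

import numpy as np
import pytest

from uwbfall import SercnetConfig, build_model, predict, train
from uwbfall.sercnet import (
    DenseResidualBlock,
    load_checkpoint,
    save_checkpoint,
    se_recalibrate,
)

TINY = dict(
    n_classes=2,
    input_size=16,
    n_blocks=2,
    channels_per_block=(4, 6),
    se_reduction=2,
    epochs=20,
    batch_size=8,
    learning_rate=3e-3,
    seed=0,
)


def blob_dataset(n_per_class=15, size=16, seed=0):
    """Linearly separable toy images: bright blob left vs right."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = rng.random((size, size)).astype(np.float32) * 0.1
            col = rng.integers(1, size // 2 - 1) + (
                0 if label == 0 else size // 2
            )
            row = rng.integers(2, size - 2)
            img[row - 1 : row + 2, col - 1 : col + 2] += 0.9
            xs.append(np.clip(img, 0, 1))
            ys.append(label)
    return np.stack(xs), np.array(ys)


class TestSeRecalibrate:
    def test_zero_parameters_halve_input(self):
        f = np.random.default_rng(0).normal(size=(5, 5, 3))
        c, cr = 3, 2
        out = se_recalibrate(
            f, np.zeros((cr, c)), np.zeros(cr), np.zeros((c, cr)), np.zeros(c)
        )
        assert np.allclose(out, 0.5 * f)

    def test_gates_bounded_below_one(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(4, 4, 6))
        out = se_recalibrate(
            f, rng.normal(size=(3, 6)), rng.normal(size=3),
            rng.normal(size=(6, 3)), rng.normal(size=6),
        )
        in_mag = np.abs(f).sum(axis=(0, 1))
        out_mag = np.abs(out).sum(axis=(0, 1))
        assert np.all(out_mag <= in_mag + 1e-12)

    def test_hand_set_gate_value(self):
        # single channel, constant-1 input, pre-sigmoid activation = 2
        f = np.ones((3, 3, 1))
        w1 = np.ones((1, 1))
        b1 = np.zeros(1)
        w2 = np.ones((1, 1))
        b2 = np.ones(1)  # z=1 -> h=1 -> pre-sigmoid = 1*1+1 = 2
        out = se_recalibrate(f, w1, b1, w2, b2)
        gate = 1.0 / (1.0 + np.exp(-2.0))
        assert np.allclose(out, gate)
        assert gate == pytest.approx(0.8808, abs=1e-4)


class TestArchitecture:
    def test_block_halves_spatial_size(self):
        rng = np.random.default_rng(0)
        blk = DenseResidualBlock(3, 4, SercnetConfig(**{**TINY, "n_blocks": 1,
                                 "channels_per_block": (4,)}), rng)
        out = blk.forward(rng.normal(size=(2, 3, 80, 80)).astype(np.float32),
                          train=False)
        assert out.shape == (2, 7, 40, 40)  # concat: 3 + 4 channels

    def test_six_blocks_reduce_80_to_1(self):
        cfg = SercnetConfig()
        net = build_model(cfg)
        s = cfg.input_size
        for _ in range(cfg.n_blocks):
            s //= 2
        assert s == 1
        x = np.zeros((2, 1, 80, 80), dtype=np.float32)
        logits = net.forward(x)
        assert logits.shape == (2, 10)
        assert np.all(np.isfinite(logits))

    def test_logits_width_follows_n_classes(self):
        cfg = SercnetConfig(**{**TINY, "n_classes": 7})
        net = build_model(cfg)
        out = net.forward(np.zeros((3, 1, 16, 16), dtype=np.float32))
        assert out.shape == (3, 7)

    def test_n_blocks_respected(self):
        net = build_model(SercnetConfig(**TINY))
        assert len(net.blocks) == TINY["n_blocks"]

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError, match="input_size"):
            SercnetConfig(**{**TINY, "n_blocks": 5,
                             "channels_per_block": (4,) * 5})

    def test_additive_merge_channel_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        cfg = SercnetConfig(**{**TINY, "merge": "add"})
        with pytest.raises(ValueError, match="merge"):
            DenseResidualBlock(3, 4, cfg, rng)

    def test_se_identity_limit_equals_plain_residual(self):
        """With gates pinned to 1 the block is the plain residual block."""
        rng = np.random.default_rng(3)
        cfg = SercnetConfig(**TINY)
        blk = DenseResidualBlock(2, 4, cfg, rng)
        x = rng.normal(size=(2, 2, 16, 16)).astype(np.float32)
        blk.se.enabled = False
        got = blk.forward(x, train=False)
        # plain residual path computed from the same sublayers
        out1 = blk.relu1.forward(
            blk.bn1.forward(blk.conv1.forward(x, False), False), False
        )
        out2 = blk.relu2.forward(
            blk.bn2.forward(blk.conv2.forward(out1, False), False), False
        )
        merged = np.concatenate([x, out1 + out2], axis=1)
        expected = blk.pool.forward(merged, False)
        assert np.allclose(got, expected)

    def test_parameter_count_reported(self):
        net = build_model(SercnetConfig(**TINY))
        assert net.n_parameters() == sum(p.size for p in net.parameters())
        assert net.n_parameters() > 0


class TestPredict:
    def test_batch_shape(self):
        net = build_model(SercnetConfig(**TINY))
        x = np.random.default_rng(0).random((5, 16, 16)).astype(np.float32)
        z = predict(net, (x, None))
        assert z.shape == (5, 2)

    def test_duplicates_and_permutation(self):
        net = build_model(SercnetConfig(**TINY))
        rng = np.random.default_rng(1)
        x = rng.random((6, 16, 16)).astype(np.float32)
        x[3] = x[0]
        z = predict(net, (x, None))
        assert np.allclose(z[3], z[0])
        perm = rng.permutation(6)
        zp = predict(net, (x[perm], None))
        assert np.allclose(zp, z[perm], atol=1e-5)

    def test_shape_mismatch_rejected(self):
        net = build_model(SercnetConfig(**TINY))
        with pytest.raises(ValueError, match="expected"):
            net.forward(np.zeros((2, 1, 8, 8), dtype=np.float32))


class TestTraining:
    def test_separable_toy_problem_learned(self):
        x, y = blob_dataset()
        cfg = SercnetConfig(**TINY)
        net = build_model(cfg)
        tm = train(net, (x, y), (x[:6], y[:6]), cfg)
        assert tm.history["train_acc"][-1] == 1.0
        assert len(tm.history["train_loss"]) == cfg.epochs

    def test_loss_decreases_after_warmup(self):
        x, y = blob_dataset(seed=2)
        cfg = SercnetConfig(**TINY)
        net = build_model(cfg)
        tm = train(net, (x, y), (x[:6], y[:6]), cfg)
        loss = np.array(tm.history["train_loss"])
        # non-increasing after the first epochs, within 5% spikes
        tail = loss[5:]
        assert np.all(tail[1:] <= tail[:-1] * 1.05)

    def test_seed_determinism(self):
        x, y = blob_dataset(seed=3)
        cfg = SercnetConfig(**{**TINY, "epochs": 4})
        h1 = train(build_model(cfg), (x, y), (x[:6], y[:6]), cfg).history
        h2 = train(build_model(cfg), (x, y), (x[:6], y[:6]), cfg).history
        assert h1 == h2

    def test_zero_learning_rate_leaves_model_untouched(self):
        x, y = blob_dataset(seed=4)
        cfg = SercnetConfig(**{**TINY, "epochs": 3, "learning_rate": 0.0})
        net = build_model(cfg)
        before = [p.copy() for p in net.parameters()]
        z_before = predict(net, (x, None))
        tm = train(net, (x, y), (x[:6], y[:6]), cfg)
        for p, q in zip(tm.model.parameters(), before):
            assert np.array_equal(p, q)
        assert np.allclose(predict(tm, (x, None)), z_before)

    def test_empty_split_rejected(self):
        cfg = SercnetConfig(**TINY)
        net = build_model(cfg)
        with pytest.raises(ValueError, match="empty"):
            train(net, (np.zeros((0, 16, 16)), np.zeros(0, dtype=int)),
                  (np.zeros((1, 16, 16)), np.zeros(1, dtype=int)), cfg)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        x, y = blob_dataset(n_per_class=5)
        cfg = SercnetConfig(**{**TINY, "epochs": 2})
        tm = train(build_model(cfg), (x, y), (x[:4], y[:4]), cfg)
        save_checkpoint(tm, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        assert np.allclose(
            predict(back, (x, None)), predict(tm, (x, None)), atol=1e-6
        )
        assert back.history == tm.history
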