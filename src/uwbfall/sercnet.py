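"""SE-RCNet: a squeeze-and-excite residual CNN for radar-map classification.

Architecture: an initial 3×3 convolution + ReLU, followed by ``n_blocks``
densely-connected residual blocks, a flatten, and a dense softmax head.
Each block runs two conv→BN→ReLU stages, adds their outputs element-wise
(residual learning), recalibrates the sum with a squeeze-and-excite
module, merges the result with the block input (channel concatenation by
default — the "dense" connection — or element-wise addition), and ends
with 2×2 max-pooling.  Six blocks reduce an 80×80 input to 1×1
(80→40→20→10→5→2→1 with floor halving).

The classifier head emits raw logits; softmax probabilities and
confidences are the fusion stage's job (:mod:`uwbfall.fusion`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._nn import (
    Adam,
    BatchNorm,
    Conv3x3,
    Dense,
    MaxPool2,
    ReLU,
    SqueezeExcite,
    _sigmoid,
    softmax_xent,
)
from .preprocess import RadarImage

F32 = np.float32


@dataclass
class SercnetConfig:
    """Hyper-parameters of the SE-RCNet classifier.

    The defaults (3×3 kernels, channels 16..96, SE reduction 4, Adam at
    1e-3, batch 32) are the package's reference configuration; all are
    exposed because smaller settings are routinely used for CPU-scale
    experiments.
    """

    n_classes: int = 10
    input_size: int = 80
    input_channels: int = 1
    n_blocks: int = 6
    channels_per_block: Tuple[int, ...] = (16, 32, 48, 64, 80, 96)
    se_reduction: int = 4
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    merge: str = "concat"  # "concat" (dense connection) or "add"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks: must be >= 1")
        if len(self.channels_per_block) < self.n_blocks:
            raise ValueError(
                "channels_per_block: need at least one entry per block, got "
                f"{len(self.channels_per_block)} for {self.n_blocks} blocks"
            )
        if self.se_reduction < 1:
            raise ValueError("se_reduction: must be >= 1")
        if self.merge not in ("concat", "add"):
            raise ValueError(f"merge: unknown mode {self.merge!r}")
        s = self.input_size
        for i in range(self.n_blocks):
            if s < 2:
                raise ValueError(
                    f"input_size: spatial size collapses to {s} before "
                    f"block {i + 1}; reduce n_blocks or enlarge the input"
                )
            s //= 2


class DenseResidualBlock:
    """conv→BN→ReLU ×2, residual sum, SE gate, merge with input, max-pool."""

    def __init__(self, c_in: int, c_res: int, cfg: SercnetConfig,
                 rng: np.random.Generator):
        if cfg.merge == "add" and c_res != c_in:
            raise ValueError(
                "merge: additive merge requires equal channel counts, got "
                f"{c_in} in vs {c_res} residual"
            )
        self.merge = cfg.merge
        self.conv1 = Conv3x3(c_in, c_res, rng)
        self.bn1 = BatchNorm(c_res)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(c_res, c_res, rng)
        self.bn2 = BatchNorm(c_res)
        self.relu2 = ReLU()
        self.se = SqueezeExcite(c_res, cfg.se_reduction, rng)
        self.pool = MaxPool2()
        self.c_out = c_in + c_res if cfg.merge == "concat" else c_res

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out1 = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        out2 = self.relu2.forward(
            self.bn2.forward(self.conv2.forward(out1, train), train), train
        )
        s = self.se.forward(out1 + out2, train)
        merged = (
            np.concatenate([x, s], axis=1) if self.merge == "concat" else x + s
        )
        return self.pool.forward(merged, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dm = self.pool.backward(dy)
        if self.merge == "concat":
            c_in = dm.shape[1] - self.se.w2.shape[0]
            dx_skip, ds = dm[:, :c_in], dm[:, c_in:]
        else:
            dx_skip, ds = dm, dm
        dsum = self.se.backward(np.ascontiguousarray(ds))
        dout1_b = self.conv2.backward(
            self.bn2.backward(self.relu2.backward(dsum))
        )
        dout1 = dsum + dout1_b
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dout1)))
        return dx + dx_skip

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.se]


class SERCNet:
    """The assembled network; forward maps (N, C, H, W) → (N, K) logits."""

    def __init__(self, cfg: SercnetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv0 = Conv3x3(cfg.input_channels, cfg.channels_per_block[0], rng)
        self.relu0 = ReLU()
        self.blocks: List[DenseResidualBlock] = []
        c = cfg.channels_per_block[0]
        s = cfg.input_size
        for i in range(cfg.n_blocks):
            blk = DenseResidualBlock(c, cfg.channels_per_block[i], cfg, rng)
            self.blocks.append(blk)
            c = blk.c_out
            s //= 2
        self.flat_dim = c * s * s
        self.head = Dense(self.flat_dim, cfg.n_classes, rng)

    # -- plumbing -----------------------------------------------------

    def _layers(self):
        out = [self.conv0]
        for b in self.blocks:
            out.extend(b.layers())
        out.append(self.head)
        return out

    def parameters(self) -> List[np.ndarray]:
        return [p for l in self._layers() for p in l.params()]

    def gradients(self) -> List[np.ndarray]:
        return [g for l in self._layers() for g in l.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        state = {"params": [p.copy() for p in self.parameters()], "bn": []}
        for l in self._layers():
            if isinstance(l, BatchNorm):
                state["bn"].append(
                    (l.running_mean.copy(), l.running_var.copy())
                )
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, q in zip(self.parameters(), state["params"]):
            p[...] = q
        bns = [l for l in self._layers() if isinstance(l, BatchNorm)]
        for l, (m, v) in zip(bns, state["bn"]):
            l.running_mean[...] = m
            l.running_var[...] = v

    # -- forward/backward ---------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != self.cfg.input_channels or x.shape[2:] != (
            self.cfg.input_size,
            self.cfg.input_size,
        ):
            raise ValueError(
                f"expected (N, {self.cfg.input_channels}, "
                f"{self.cfg.input_size}, {self.cfg.input_size}), got {x.shape}"
            )
        h = self.relu0.forward(self.conv0.forward(x, train), train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.head.forward(h.reshape(h.shape[0], -1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        n = dh.shape[0]
        side = self.cfg.input_size // (2 ** self.cfg.n_blocks)
        dh = dh.reshape(n, -1, side, side)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.conv0.backward(self.relu0.backward(dh))


@dataclass
class TrainedModel:
    """A trained network, its configuration, and the training history."""

    model: SERCNet
    config: SercnetConfig
    history: Dict[str, List[float]] = field(default_factory=dict)


def se_recalibrate(
    features: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Squeeze-and-excite recalibration of a single (H, W, C) feature stack.

    Squeeze: per-channel spatial mean.  Excite: C→C/r linear, ReLU,
    C/r→C linear, sigmoid → per-channel gates in (0, 1) multiplying the
    input channels.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 3:
        raise ValueError("features must be (H, W, C)")
    z = f.mean(axis=(0, 1))
    h = np.maximum(np.asarray(w1) @ z + b1, 0.0)
    g = _sigmoid(np.asarray(w2) @ h + b2)
    return f * g[None, None, :]


def build_model(cfg: SercnetConfig) -> SERCNet:
    """Construct an SE-RCNet from its configuration (validated)."""
    return SERCNet(cfg)


def _as_arrays(
    data: Union[Tuple[np.ndarray, np.ndarray], Sequence[RadarImage]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays or a sequence of labeled RadarImages."""
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[:, None]
        y = np.full(len(x), -1) if y is None else np.asarray(y, dtype=int)
        return x, y
    x = np.stack([np.asarray(im.pixels, dtype=F32) for im in data])[:, None]
    y = np.array([im.label for im in data], dtype=int)
    return x, y


def predict(model: Union[SERCNet, TrainedModel], images,
            batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode logits for a batch of images, shape (N, n_classes)."""
    net = model.model if isinstance(model, TrainedModel) else model
    if isinstance(images, tuple):
        x, _ = _as_arrays(images)
    elif isinstance(images, np.ndarray):
        x = np.asarray(images, dtype=F32)
        if x.ndim == 3:
            x = x[:, None]
    else:
        x, _ = _as_arrays((np.stack([im.pixels for im in images]), None))
    out = [net.forward(x[i : i + batch_size], train=False)
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def train(
    model: SERCNet,
    train_set,
    val_set,
    cfg: Optional[SercnetConfig] = None,
) -> TrainedModel:
    """Train with Adam on softmax cross-entropy; return best-val weights.

    Deterministic for a fixed ``cfg.seed``: initialization and the
    shuffling stream both derive from it.  With ``learning_rate == 0``
    the model is left untouched (no parameter or statistics updates), so
    the returned model equals the untrained one.
    """
    cfg = cfg or model.cfg
    xtr, ytr = _as_arrays(train_set)
    xva, yva = _as_arrays(val_set)
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("empty train or validation split")
    if ytr.min() < 0 or ytr.max() >= cfg.n_classes:
        raise ValueError("labels out of range")

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x5E5E]).generate_state(1)[0]
    )
    updating = cfg.learning_rate > 0.0
    history: Dict[str, List[float]] = {
        "train_loss": [], "train_acc": [], "val_acc": []
    }
    best = (-1.0, model.state_dict())
    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(xtr))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logits = model.forward(xb, train=updating)
            loss, dlogits = softmax_xent(logits, yb)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
            if updating:
                model.backward(dlogits)
                opt.step(model.gradients())
        val_logits = predict(model, (xva, yva))
        val_acc = float((val_logits.argmax(axis=1) == yva).mean())
        history["train_loss"].append(float(np.sum(losses) / len(xtr)))
        history["train_acc"].append(correct / len(xtr))
        history["val_acc"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, model.state_dict())
    model.load_state_dict(best[1])
    return TrainedModel(model=model, config=cfg, history=history)


def save_checkpoint(tm: TrainedModel, out_dir) -> None:
    """NPZ weight file plus a JSON sidecar with config and history."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = tm.model.state_dict()
    arrays = {f"p{i}": p for i, p in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn"]):
        arrays[f"bn{i}_mean"] = m
        arrays[f"bn{i}_var"] = v
    np.savez(out / "weights.npz", **arrays)
    meta = {"config": asdict(tm.config), "history": tm.history}
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(out_dir) -> TrainedModel:
    out = Path(out_dir)
    meta = json.loads((out / "model.json").read_text())
    ckw = meta["config"]
    ckw["channels_per_block"] = tuple(ckw["channels_per_block"])
    cfg = SercnetConfig(**ckw)
    net = SERCNet(cfg)
    data = np.load(out / "weights.npz")
    n_params = len(net.parameters())
    state = {
        "params": [data[f"p{i}"] for i in range(n_params)],
        "bn": [],
    }
    i = 0
    while f"bn{i}_mean" in data:
        state["bn"].append((data[f"bn{i}_mean"], data[f"bn{i}_var"]))
        i += 1
    net.load_state_dict(state)
    return TrainedModel(model=net, config=cfg, history=meta["history"])
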