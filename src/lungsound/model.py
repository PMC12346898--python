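"""Residual-CNN (+ optional LSTM) classifier for fused auscultation features.

The backbone follows the ResNet-18 template — a 7x7 stride-2 stem with
batch-norm, ReLU and 3x3 max-pooling, then four stages of two residual
blocks (3x3 convolutions) — but with configurable stage widths defaulting
to (16, 32, 64, 128). The canonical (64, ..., 512) widths give an ~11 M
parameter network; the narrowed stack lands in the few-million range
appropriate for a 3-class problem and trains on a CPU.

Each residual block computes ``y = F(x, W) + x`` with
``F = conv-bn-relu-conv-bn`` and a 1x1 projection on the skip path when the
shape changes; the addition is NOT followed by an activation so the
identity limit (zeroed F) is exact.

After the stages, average pooling collapses the frequency (row) axis only,
leaving a per-column feature sequence. The ``*_lstm_*`` variants feed that
sequence to a single 64-unit LSTM; the plain CNN variants flatten it. The
head is dropout(0.3) -> fully connected -> softmax over the 3 classes
(0 = normal, 1 = wheeze, 2 = fine crackle).

Four variants cover the ablation grid: ``cnn_ts`` / ``cnn_lstm_ts`` consume
resized raw time-series grids, ``cnn_mfcc`` / ``cnn_lstm_mfcc`` the fused
MFCC input; architecturally the two input kinds differ only upstream, in
how the 128 x 350 grid was built.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .features import MODEL_INPUT_SHAPE, ModelInput, _resize_bilinear
from .vocab import INDEX_TO_LABEL

__all__ = [
    "ModelConfig",
    "Prediction",
    "ResidualBlock",
    "LungSoundNet",
    "build_model",
    "predict",
    "predict_batch",
    "activation_map",
    "describe",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("cnn_ts", "cnn_lstm_ts", "cnn_mfcc", "cnn_lstm_mfcc")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "cnn_lstm_mfcc"
    stage_widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    blocks_per_stage: int = 2
    lstm_layers: int = 1
    lstm_hidden: int = 64
    dropout: float = 0.3
    n_classes: int = 3
    input_shape: tuple[int, int] = MODEL_INPUT_SHAPE

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes != 3:
            raise ValueError("this classifier is defined for the 3-class problem")
        if self.lstm_layers != 1:
            raise ValueError("only a single stacked LSTM layer is supported")

    @property
    def uses_lstm(self) -> bool:
        return "lstm" in self.variant

    @property
    def input_kind(self) -> str:
        return "timeseries" if self.variant.endswith("_ts") else "mfcc"


@dataclass
class Prediction:
    class_probs: np.ndarray
    predicted_class: int

    @property
    def predicted_label(self) -> str:
        return INDEX_TO_LABEL[self.predicted_class]


class ResidualBlock(nn.Layer):
    """y = F(x, W) + shortcut(x); the shortcut is a 1x1 projection when the
    stride or width changes, the identity otherwise."""

    def __init__(self, c_in, c_out, stride=1, *, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj_conv = nn.Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm2d(c_out)
        else:
            self.proj_conv = self.proj_bn = None

    @property
    def has_projection(self) -> bool:
        return self.proj_conv is not None

    def residual(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu.forward(h, train)
        h = self.conv2.forward(h, train)
        return self.bn2.forward(h, train)

    def forward(self, x, train=False):
        f = self.residual(x, train)
        if self.proj_conv is not None:
            s = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            s = x
        if f.shape != s.shape:
            raise ValueError(f"residual/skip shape mismatch: {f.shape} vs {s.shape}")
        return f + s

    def backward(self, dy):
        df = self.bn2.backward(dy)
        df = self.conv2.backward(df)
        df = self.relu.backward(df)
        df = self.bn1.backward(df)
        dx = self.conv1.backward(df)
        if self.proj_conv is not None:
            dx = dx + self.proj_conv.backward(self.proj_bn.backward(dy))
        else:
            dx = dx + dy
        return dx

    def params(self):
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.proj_conv is not None:
            ps += self.proj_conv.params() + self.proj_bn.params()
        return ps


class LungSoundNet:
    """The assembled classifier; layers run in a fixed list so forward and
    backward are simple folds. The output of the last residual stage and its
    gradient are captured for class-activation mapping."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))
        w = config.stage_widths
        self.stem = [
            nn.Conv2d(1, w[0], 7, stride=2, pad=3, rng=rng),
            nn.BatchNorm2d(w[0]),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        ]
        self.stages: list[ResidualBlock] = []
        c_in = w[0]
        for s, width in enumerate(w):
            for b in range(config.blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                self.stages.append(ResidualBlock(c_in, width, stride, rng=rng))
                c_in = width
        self.row_pool = nn.RowMeanPool()
        h, wid = config.input_shape
        seq_len = wid
        for _ in range(5):  # stem conv, maxpool, stages 2-4 each halve columns
            seq_len = (seq_len + 1) // 2
        self.seq_len = seq_len
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xD0]))
        if config.uses_lstm:
            self.lstm = nn.LSTM(w[-1], config.lstm_hidden, rng=rng)
            head_in = config.lstm_hidden
        else:
            self.lstm = None
            head_in = w[-1] * seq_len
        self.dropout = nn.Dropout(config.dropout, rng=self.dropout_rng)
        self.fc = nn.Linear(head_in, config.n_classes, rng=rng)
        self._cam_act = None
        self._cam_grad = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (batch, 1, H, W) -> logits (batch, n_classes)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != self.config.input_shape:
            raise ValueError(
                f"expected (n, 1, {self.config.input_shape[0]}, {self.config.input_shape[1]}) input, got {x.shape}"
            )
        for layer in self.stem:
            x = layer.forward(x, train)
        for block in self.stages:
            x = block.forward(x, train)
        self._cam_act = x
        seq = self.row_pool.forward(x, train=True)  # cheap; keep cache for CAM
        seq = np.ascontiguousarray(seq.transpose(0, 2, 1))  # (n, T, C)
        if self.lstm is not None:
            feat = self.lstm.forward(seq, train or self._want_cam)
        else:
            self._flat_shape = seq.shape
            feat = seq.reshape(seq.shape[0], -1)
        feat = self.dropout.forward(feat, train)
        return self.fc.forward(feat, train or self._want_cam)

    _want_cam = False

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from logits; parameter grads accumulate in place."""
        d = self.fc.backward(np.ascontiguousarray(dlogits, dtype=np.float32))
        d = self.dropout.backward(d)
        if self.lstm is not None:
            dseq = self.lstm.backward(d)
        else:
            dseq = d.reshape(self._flat_shape)
        d = self.row_pool.backward(np.ascontiguousarray(dseq.transpose(0, 2, 1)))
        self._cam_grad = d
        if self._want_cam:
            return  # CAM needs only the gradient at the last stage
        for block in reversed(self.stages):
            d = block.backward(d)
        for layer in reversed(self.stem):
            d = layer.backward(d)

    def params(self) -> list[nn.Param]:
        ps = []
        for layer in self.stem + self.stages + [self.fc]:
            ps += layer.params()
        if self.lstm is not None:
            ps += self.lstm.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        k = 0
        for layer in self.stem + self.stages:
            for bn in _batchnorms_of(layer):
                state[f"bn_{k}_mean"] = bn.running_mean
                state[f"bn_{k}_var"] = bn.running_var
                k += 1
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"param_{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        k = 0
        for layer in self.stem + self.stages:
            for bn in _batchnorms_of(layer):
                bn.running_mean = np.array(state[f"bn_{k}_mean"], dtype=np.float32)
                bn.running_var = np.array(state[f"bn_{k}_var"], dtype=np.float32)
                k += 1


def _batchnorms_of(layer):
    if isinstance(layer, nn.BatchNorm2d):
        return [layer]
    if isinstance(layer, ResidualBlock):
        bns = [layer.bn1, layer.bn2]
        if layer.proj_bn is not None:
            bns.append(layer.proj_bn)
        return bns
    return []


def build_model(config: ModelConfig, seed: int = 0) -> LungSoundNet:
    """Construct a seeded, reproducible network for the given variant."""
    return LungSoundNet(config, seed)


def _as_batch(model_input) -> np.ndarray:
    grid = model_input.grid if isinstance(model_input, ModelInput) else np.asarray(model_input)
    return grid[None, None].astype(np.float32)


def predict(model: LungSoundNet, model_input) -> Prediction:
    """Deterministic single-example inference (dropout off).

    Ties in the probabilities resolve to the lowest class index.
    """
    logits = model.forward(_as_batch(model_input), train=False)
    probs = nn.softmax(logits.astype(np.float64))[0]
    return Prediction(class_probs=probs, predicted_class=int(np.argmax(probs)))


def predict_batch(model: LungSoundNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Class indices for a (n, 1, H, W) stack of inputs."""
    out = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        out.append(np.argmax(logits, axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def activation_map(model: LungSoundNet, model_input, target_class: int) -> np.ndarray:
    """Gradient-weighted class-activation map over the last residual stage.

    Channel weights are the spatial means of the class-score gradient at the
    final stage; the weighted, ReLU-rectified sum is bilinearly upsampled to
    the input shape and min-max normalised to [0, 1]. A map with no positive
    evidence comes back all-zero.
    """
    x = _as_batch(model_input)
    model._want_cam = True
    try:
        logits = model.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[0, int(target_class)] = 1.0
        model.backward(dlogits)
    finally:
        model._want_cam = False
    for p in model.params():
        p.grad[...] = 0.0  # inference must not leave gradients behind
    act = model._cam_act[0]  # (C, h, w)
    grad = model._cam_grad[0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum(0.0, np.tensordot(weights, act, axes=1))
    cam = _resize_bilinear(cam.astype(np.float64), model.config.input_shape)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        return np.zeros(model.config.input_shape)
    return cam / peak


def describe(model: LungSoundNet) -> str:
    """Layer table and parameter count."""
    lines = [
        f"variant: {model.config.variant}",
        f"input: 1 x {model.config.input_shape[0]} x {model.config.input_shape[1]}",
        "",
        f"{'layer':<28}{'params':>10}",
    ]

    def row(name, n):
        lines.append(f"{name:<28}{n:>10d}")

    row("stem conv7x7/2 + bn", sum(p.size for l in model.stem for p in l.params()))
    for i, blk in enumerate(model.stages):
        tag = " (proj)" if blk.has_projection else ""
        row(f"resblock {i + 1}{tag}", sum(p.size for p in blk.params()))
    row("row-mean pool", 0)
    if model.lstm is not None:
        row(f"lstm ({model.config.lstm_hidden} hidden)", sum(p.size for p in model.lstm.params()))
    else:
        row("flatten", 0)
    row(f"dropout p={model.config.dropout}", 0)
    row("fc + softmax", sum(p.size for p in model.fc.params()))
    lines.append("")
    lines.append(f"total parameters: {model.n_parameters():,}")
    return "\n".join(lines)


def save_checkpoint(model: LungSoundNet, path) -> None:
    """Single-file checkpoint embedding weights, config and build seed."""
    path = Path(path)
    meta = {"config": asdict(model.config), "seed": model.seed}
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_arrays())


def load_checkpoint(path) -> LungSoundNet:
    path = Path(path)
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz", allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["stage_widths"] = tuple(cfg["stage_widths"])
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = LungSoundNet(ModelConfig(**cfg), seed=meta["seed"])
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model
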