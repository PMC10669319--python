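"""Shuffle-style convolutional feature extractor.

A ShuffleNet-v1-style network: a 3x3/stride-2 stem with 24 filters, a max
pool, three stages of shuffle units (4/8/4 = 16 units total), global average
pooling, and a fully connected softmax head. Each unit is two 1x1 pointwise
group convolutions around a 3x3 depthwise convolution, with a channel
shuffle after the first pointwise conv; stride-2 units concatenate a 3x3
average-pooled shortcut, stride-1 units add an identity shortcut.

At full scale (224 px, width 1.0) the network counts 16 shuffle units and
50 learnable layers under the counting rule "convolutions (49) + the fully
connected layer (1)". The desk-scale variant (64 px, width 0.25) keeps the
topology but is small enough to train on a CPU in seconds; it feeds the
penultimate pooled activations to the fuzzy classifier downstream.

Runs on the package's own NumPy layer runtime (:mod:`epoadl._nn`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn as nn

__all__ = [
    "ConvSpec",
    "ShuffleUnitSpec",
    "BackboneConfig",
    "TrainHyperparams",
    "FeatureMatrix",
    "conv_output_size",
    "conv2d",
    "relu",
    "channel_shuffle",
    "ShuffleUnit",
    "ShuffleBackbone",
    "build_backbone",
    "train_backbone",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]

# stage output channels of ShuffleNet v1 by group count, width 1.0
_STAGE_CHANNELS = {
    1: (144, 288, 576),
    2: (200, 400, 800),
    3: (240, 480, 960),
    4: (272, 544, 1088),
    8: (384, 768, 1536),
}


@dataclass(frozen=True)
class ConvSpec:
    kernel: int
    stride: int
    padding: int
    groups: int
    in_channels: int
    out_channels: int

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise ValueError("require kernel, stride >= 1 and padding >= 0")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("channel counts must be divisible by groups")


@dataclass(frozen=True)
class ShuffleUnitSpec:
    groups: int
    stride: int
    in_channels: int
    out_channels: int
    bottleneck_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError("shuffle-unit stride must be 1 or 2")
        if self.stride == 1 and self.in_channels != self.out_channels:
            raise ValueError("stride-1 units need matching in/out channels")


@dataclass(frozen=True)
class BackboneConfig:
    """Network shape. ``stage_units`` totals 16 at the defaults."""

    input_size: int = 224
    stage_units: tuple[int, int, int] = (4, 8, 4)
    groups: int = 3
    width_scale: float = 1.0
    n_classes: int = 2

    @classmethod
    def desk(cls, **kw) -> "BackboneConfig":
        """CPU-scale variant: 64 px input, quarter width, same topology."""
        kw.setdefault("input_size", 64)
        kw.setdefault("width_scale", 0.25)
        return cls(**kw)

    def stage_channels(self) -> tuple[int, ...]:
        base = _STAGE_CHANNELS[self.groups]
        return tuple(int(round(c * self.width_scale)) for c in base)

    def stem_channels(self) -> int:
        return max(int(round(24 * self.width_scale)), self.groups)


@dataclass(frozen=True)
class TrainHyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 1e-5
    epochs: int = 8
    seed: int = 0


@dataclass
class FeatureMatrix:
    """Pooled penultimate activations, one row per image."""

    values: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


def conv_output_size(i: int, k: int, p: int, s: int) -> int:
    """Standard convolution arithmetic: floor((i - k + 2p)/s) + 1."""
    out = (i - k + 2 * p) // s + 1
    if out <= 0:
        raise ValueError(f"non-positive output size for i={i}, k={k}, p={p}, s={s}")
    return out


def conv2d(image: np.ndarray, kernel: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Plain single-channel cross-correlation (sliding sum of products)."""
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    k = kernel.shape[0]
    out_h = conv_output_size(image.shape[0], k, padding, stride)
    out_w = conv_output_size(image.shape[1], kernel.shape[1], padding, stride)
    if padding:
        image = np.pad(image, padding)
    out = np.empty((out_h, out_w))
    for r in range(out_h):
        for c in range(out_w):
            patch = image[r * stride : r * stride + k, c * stride : c * stride + kernel.shape[1]]
            out[r, c] = np.sum(patch * kernel)
    return out


def relu(x):
    """max(0, x)."""
    return np.maximum(0, x)


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Permute channels by reshaping (g, C/g), transposing and flattening.

    Accepts NCHW (channel axis 1) or any array whose first axis is channels.
    Applying the shuffle again with ``C // groups`` restores the original
    order (the permutation's inverse).
    """
    x = np.asarray(x)
    axis = 1 if x.ndim == 4 else 0
    C = x.shape[axis]
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    perm = np.arange(C).reshape(groups, C // groups).T.reshape(-1)
    return np.take(x, perm, axis=axis)


class ShuffleUnit(nn.Module):
    """One shuffle unit; see the module docstring for the layer order."""

    def __init__(self, spec: ShuffleUnitSpec, rng):
        super().__init__()
        self.spec = spec
        g = spec.groups
        branch_out = spec.out_channels - (spec.in_channels if spec.stride == 2 else 0)
        mid = int(spec.out_channels * spec.bottleneck_ratio)
        if mid % g or branch_out % g or spec.in_channels % g:
            raise ValueError("unit channels must divide the group count")
        self.conv1 = nn.Conv2d(spec.in_channels, mid, 1, groups=g, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.relu1 = nn.ReLU()
        self.shuffle = nn.ChannelShuffle(g)
        self.dw = nn.DepthwiseConv2d(mid, 3, stride=spec.stride, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, branch_out, 1, groups=g, rng=rng)
        self.bn3 = nn.BatchNorm2d(branch_out)
        self.relu_out = nn.ReLU()
        self.shortcut_pool = nn.AvgPool2d(3, 2, 1) if spec.stride == 2 else None

    def children(self):
        ch = [self.conv1, self.bn1, self.relu1, self.shuffle, self.dw, self.bn2, self.conv3, self.bn3, self.relu_out]
        if self.shortcut_pool is not None:
            ch.append(self.shortcut_pool)
        return ch

    def forward(self, x):
        branch = self.bn3.forward(
            self.conv3.forward(
                self.bn2.forward(
                    self.dw.forward(
                        self.shuffle.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x))))
                    )
                )
            )
        )
        if self.spec.stride == 2:
            short = self.shortcut_pool.forward(x)
            self._split = short.shape[1]
            y = np.concatenate([short, branch], axis=1)
        else:
            self._x = x
            y = x + branch
        return self.relu_out.forward(y)

    def backward(self, gout):
        g = self.relu_out.backward(gout)
        if self.spec.stride == 2:
            g_short, g_branch = g[:, : self._split], g[:, self._split :]
            gx = self.shortcut_pool.backward(np.ascontiguousarray(g_short))
            g_branch = np.ascontiguousarray(g_branch)
        else:
            gx = g
            g_branch = g
        gb = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.shuffle.backward(
                        self.dw.backward(self.bn2.backward(self.conv3.backward(self.bn3.backward(g_branch))))
                    )
                )
            )
        )
        return gx + gb


class ShuffleBackbone(nn.Module):
    """Stem -> max pool -> 3 stages of shuffle units -> GAP -> FC head."""

    def __init__(self, config: BackboneConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng()
        stem = config.stem_channels()
        self.stem = nn.Conv2d(3, stem, 3, stride=2, pad=1, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.units: list[ShuffleUnit] = []
        in_ch = stem
        for n_units, out_ch in zip(config.stage_units, config.stage_channels()):
            for u in range(n_units):
                stride = 2 if u == 0 else 1
                spec = ShuffleUnitSpec(config.groups, stride, in_ch, out_ch)
                self.units.append(ShuffleUnit(spec, rng))
                in_ch = out_ch
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, config.n_classes, rng=rng)
        self.feature_dim = in_ch

    def children(self):
        return [self.stem, self.stem_bn, self.stem_relu, self.pool, *self.units, self.gap, self.fc]

    # --- structure bookkeeping -------------------------------------------
    def n_shuffle_units(self) -> int:
        return len(self.units)

    def n_learnable_layers(self) -> int:
        """Convolutions + fully connected layers (the documented rule)."""
        kinds = (nn.Conv2d, nn.DepthwiseConv2d, nn.Linear)
        return sum(1 for m in self.modules() if isinstance(m, kinds))

    # --- passes -----------------------------------------------------------
    def forward_features(self, x: np.ndarray) -> np.ndarray:
        h = self.pool.forward(self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x))))
        for u in self.units:
            h = u.forward(h)
        return self.gap.forward(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc.forward(self.forward_features(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.fc.backward(glogits))
        for u in reversed(self.units):
            g = u.backward(g)
        return self.stem.backward(
            self.stem_bn.backward(self.stem_relu.backward(self.pool.backward(g)))
        )


def build_backbone(config: BackboneConfig, seed: int | None = None) -> ShuffleBackbone:
    """Construct the network with He-normal weights from a seeded generator."""
    return ShuffleBackbone(config, np.random.default_rng(seed))


def _as_input(images: np.ndarray) -> np.ndarray:
    """uint8 NHWC [0,255] -> float32 NCHW, centred to [-0.5, 0.5]."""
    x = np.asarray(images, dtype=np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def train_backbone(
    model: ShuffleBackbone,
    images: np.ndarray,
    labels: np.ndarray,
    hyper: TrainHyperparams,
) -> list[dict]:
    """Mini-batch Adam on softmax cross-entropy; returns the per-epoch
    history ``[{epoch, loss, accuracy}, ...]``. Aborts on a NaN loss."""
    x = _as_input(images)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(hyper.seed)
    opt = nn.Adam(model.modules(), lr=hyper.learning_rate, weight_decay=hyper.weight_decay)
    model.set_training(True)
    history = []
    n = x.shape[0]
    for epoch in range(1, hyper.epochs + 1):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            logits = model.forward(x[idx])
            loss, glogits = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}"
                )
            model.backward(glogits)
            opt.step()
            losses.append(loss)
            correct += int(np.sum(logits.argmax(axis=1) == y[idx]))
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    recalibrate_batchnorm(model, x, batch_size=hyper.batch_size)
    model.set_training(False)
    return history


def recalibrate_batchnorm(model: ShuffleBackbone, x: np.ndarray, batch_size: int = 32) -> None:
    """Reset batch-norm running statistics to the average batch statistics of
    a full pass over ``x`` with the final weights.

    On datasets this small the exponential running estimates lag the weights
    badly by the end of training, which wrecks eval-mode accuracy; one
    recalibration pass removes the lag.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    sums = [None] * len(bns)
    counts = 0
    model.set_training(True)
    saved = [(b.running_mean, b.running_var, b.momentum) for b in bns]
    for b in bns:
        b.momentum = 1.0  # each forward overwrites running stats with batch stats
    for start in range(0, x.shape[0], batch_size):
        model.forward_features(x[start : start + batch_size])
        for i, b in enumerate(bns):
            pair = np.stack([b.running_mean, b.running_var])
            sums[i] = pair if sums[i] is None else sums[i] + pair
        counts += 1
    for b, (mean, var, momentum) in zip(bns, saved):
        b.momentum = momentum
    for i, b in enumerate(bns):
        b.running_mean = (sums[i][0] / counts).astype(np.float32)
        b.running_var = (sums[i][1] / counts).astype(np.float32)
    model.set_training(False)


def extract_features(
    model: ShuffleBackbone, images: np.ndarray, ids=None, batch_size: int = 64
) -> FeatureMatrix:
    """Penultimate pooled activations per image (eval mode, deterministic)."""
    x = _as_input(images)
    model.set_training(False)
    rows = [
        model.forward_features(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)
    ]
    values = np.concatenate(rows, axis=0).astype(np.float64)
    return FeatureMatrix(values, list(ids) if ids is not None else list(range(x.shape[0])))


def save_checkpoint(model: ShuffleBackbone, path) -> None:
    """NumPy .npz weights plus a JSON config sidecar."""
    path = Path(path)
    arrays = {}
    for i, m in enumerate(model.modules()):
        for k, v in m.params.items():
            arrays[f"{i}.{k}"] = v
        if isinstance(m, nn.BatchNorm2d):
            arrays[f"{i}.running_mean"] = m.running_mean
            arrays[f"{i}.running_var"] = m.running_var
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config)))


def load_checkpoint(path) -> ShuffleBackbone:
    path = Path(path)
    cfg_doc = json.loads(path.with_suffix(".json").read_text())
    cfg_doc["stage_units"] = tuple(cfg_doc["stage_units"])
    model = build_backbone(BackboneConfig(**cfg_doc), seed=0)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, m in enumerate(model.modules()):
        for k in m.params:
            m.params[k] = data[f"{i}.{k}"]
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean = data[f"{i}.running_mean"]
            m.running_var = data[f"{i}.running_var"]
    model.set_training(False)
    return model
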