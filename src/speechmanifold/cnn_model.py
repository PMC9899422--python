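"""Convolutional word classifiers with per-layer activation taps.

Two architectures share one small numpy layer framework (conv / batch-norm /
ReLU / max-pool / linear with hand-written backward passes and SGD-momentum
updates):

* ``resnet18`` — the standard 18-layer residual network adapted to 1-channel
  spectrogram input.  Its registry of extractable convolutional layers is the
  stem conv, the 16 block convs, and the 3 projection-shortcut convs: 20 in
  total, in forward order.
* ``tinyconv`` — a 4-conv desk-scale hierarchy (8/16/32/64 channels, 3x3,
  stride-2 max pooling) plus a linear head; it trains in CPU-seconds while
  preserving a layer hierarchy for geometry analysis.

Both condition arms of an experiment are built from identical configs; the
only permitted difference between arms is the data they see.  Training is a
pure function of (config, data, seed): fixed seeds reproduce error curves
bit-for-bit in deterministic mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .manifold_geometry import ActivationSet
from .synthetic_speech import DatasetSplit, MelSpectrogram

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "TrainedModel",
    "PredictiveDistribution",
    "build_model",
    "train",
    "predict",
    "predict_batch",
    "extract_activations",
]


@dataclass(frozen=True)
class PredictiveDistribution:
    """Probability vector over the word lexicon (softmax of class scores)."""

    probs: np.ndarray


@dataclass
class ModelConfig:
    architecture: str  # {"resnet18", "tinyconv"}
    n_classes: int
    input_shape: tuple[int, int]  # (bands, frames)
    conv_layer_registry: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")


@dataclass
class TrainingConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    optimizer_name: str = "sgd"
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


@dataclass
class TrainedModel:
    model_config: ModelConfig
    network: "object"
    training_config: TrainingConfig | None = None
    error_curve: list[float] = field(default_factory=list)

    @property
    def head(self):
        return self.network.head


# ---------------------------------------------------------------------------
# Layer framework
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad", "mom")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.mom = np.zeros_like(value)


class Conv2d:
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None):
        scale = math.sqrt(2.0 / (cin * k * k))
        self.W = Param(scale * rng.standard_normal((cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        _, _, Ho, Wo, _, _ = win.shape
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * k * k)
        Wm = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ Wm.T + self.b.value
        out = out.reshape(B, Ho, Wo, -1).transpose(0, 3, 1, 2)
        self._cache = (cols, xp.shape, (B, C, H, W), Ho, Wo)
        return out

    def backward(self, dout):
        cols, xp_shape, x_shape, Ho, Wo = self._cache
        B, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        cout = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.W.grad += (dflat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value.reshape(cout, -1)
        dcols = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[..., i, j]
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class BatchNorm2d:
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) / std[None, :, None, None]
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d:
    def __init__(self, k, stride=None, pad=0):
        self.k, self.stride, self.pad = k, (stride or k), pad

    def params(self):
        return []

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        )
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        B_, C_, Ho, Wo, _, _ = win.shape
        flat = win.reshape(B, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, xp.shape, (B, C, H, W), Ho, Wo)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        idx, xp_shape, x_shape, Ho, Wo = self._cache
        B, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(xp_shape)
        bi, ci, hi, wi = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(Ho), np.arange(Wo), indexing="ij"
        )
        rows = hi * s + idx // k
        cols = wi * s + idx % k
        np.add.at(dxp, (bi, ci, rows, cols), dout)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class Linear:
    def __init__(self, n_in, n_out, rng):
        scale = math.sqrt(2.0 / n_in)
        self.W = Param(scale * rng.standard_normal((n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


class TinyConvNet:
    """4 conv layers (8/16/32/64 ch, 3x3) with stride-2 pooling + linear head."""

    CHANNELS = (8, 16, 32, 64)

    def __init__(self, n_classes, input_shape, rng):
        H, W = input_shape
        self.convs, self.relus, self.pools = [], [], []
        cin = 1
        h, w = H, W
        for c in self.CHANNELS:
            self.convs.append(Conv2d(cin, c, 3, stride=1, pad=1, rng=rng))
            self.relus.append(ReLU())
            self.pools.append(MaxPool2d(2))
            cin = c
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ConfigurationError("input too small for tinyconv pooling depth")
        self.head = Linear(cin * h * w, n_classes, rng)
        self._flat_shape = (cin, h, w)
        self.registry = [f"conv{i + 1}" for i in range(4)]

    def params(self):
        out = []
        for c in self.convs:
            out += c.params()
        return out + self.head.params()

    def forward(self, x, train=False, taps=None):
        for i, (conv, relu, pool) in enumerate(zip(self.convs, self.relus, self.pools)):
            x = relu.forward(conv.forward(x, train), train)
            if taps is not None and f"conv{i + 1}" in taps:
                taps[f"conv{i + 1}"] = x
            x = pool.forward(x, train)
        self._pre_flat = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1), train)

    def backward(self, dout):
        dx = self.head.backward(dout).reshape(self._pre_flat)
        for conv, relu, pool in zip(self.convs[::-1], self.relus[::-1], self.pools[::-1]):
            dx = conv.backward(relu.backward(pool.backward(dx)))
        return dx


class BasicBlock:
    def __init__(self, cin, cout, stride, rng, name):
        self.name = name
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.ds_conv = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
            self.ds_bn = BatchNorm2d(cout)
        else:
            self.ds_conv = None

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.ds_conv is not None:
            out += self.ds_conv.params() + self.ds_bn.params()
        return out

    def registry(self):
        ids = [f"{self.name}.conv1", f"{self.name}.conv2"]
        if self.ds_conv is not None:
            ids.append(f"{self.name}.downsample")
        return ids

    def forward(self, x, train=False, taps=None):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        if taps is not None and f"{self.name}.conv1" in taps:
            taps[f"{self.name}.conv1"] = out
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.ds_conv is not None:
            skip = self.ds_bn.forward(self.ds_conv.forward(x, train), train)
            if taps is not None and f"{self.name}.downsample" in taps:
                taps[f"{self.name}.downsample"] = skip
        else:
            skip = x
        out = self.relu2.forward(out + skip, train)
        if taps is not None and f"{self.name}.conv2" in taps:
            taps[f"{self.name}.conv2"] = out
        return out

    def backward(self, dout):
        d = self.relu2.backward(dout)
        d_main = self.conv2.backward(self.bn2.backward(d))
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(d_main)))
        if self.ds_conv is not None:
            d_skip = self.ds_conv.backward(self.ds_bn.backward(d))
        else:
            d_skip = d
        return d_main + d_skip


class ResNet18:
    """ResNet-18 adapted to 1-channel spectrogram input.

    Registry (forward order): the stem conv, then per block conv1, conv2 and
    (stages 2-4, first block) the projection-shortcut conv — 20 layers.
    Block taps are post-nonlinearity; the shortcut tap is its batch-norm
    output (it feeds the residual sum and has no nonlinearity of its own).
    """

    def __init__(self, n_classes, input_shape, rng):
        self.conv1 = Conv2d(1, 64, 7, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2d(3, stride=2, pad=1)
        self.blocks = []
        cin = 64
        for stage, (cout, stride) in enumerate([(64, 1), (128, 2), (256, 2), (512, 2)], start=1):
            for b in range(2):
                s = stride if b == 0 else 1
                self.blocks.append(BasicBlock(cin, cout, s, rng, f"layer{stage}.{b}"))
                cin = cout
        self.avgpool = GlobalAvgPool()
        self.head = Linear(512, n_classes, rng)
        self.registry = ["conv1"]
        for blk in self.blocks:
            self.registry += blk.registry()

    def params(self):
        out = self.conv1.params() + self.bn1.params()
        for blk in self.blocks:
            out += blk.params()
        return out + self.head.params()

    def forward(self, x, train=False, taps=None):
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        if taps is not None and "conv1" in taps:
            taps["conv1"] = x
        x = self.pool1.forward(x, train)
        for blk in self.blocks:
            x = blk.forward(x, train, taps)
        return self.head.forward(self.avgpool.forward(x, train), train)

    def backward(self, dout):
        dx = self.avgpool.backward(self.head.backward(dout))
        for blk in self.blocks[::-1]:
            dx = blk.backward(dx)
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(self.pool1.backward(dx))))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

_ARCHITECTURES = {"tinyconv": TinyConvNet, "resnet18": ResNet18}


def build_model(config: ModelConfig, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained network and fill its conv-layer registry."""
    if config.architecture not in _ARCHITECTURES:
        raise ConfigurationError(
            f"unknown architecture {config.architecture!r}; "
            f"choose from {sorted(_ARCHITECTURES)}"
        )
    rng = np.random.default_rng(seed)
    net = _ARCHITECTURES[config.architecture](config.n_classes, config.input_shape, rng)
    config.conv_layer_registry = list(net.registry)
    return TrainedModel(model_config=config, network=net)


def _stack(samples: list[MelSpectrogram]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.values for s in samples])[:, None, :, :]
    # unlabeled samples (prediction-only paths) carry a -1 placeholder
    y = np.array([-1 if s.label is None else s.label for s in samples], dtype=np.int64)
    return X, y


def _check_shape(model: TrainedModel, X: np.ndarray):
    if tuple(X.shape[-2:]) != tuple(model.model_config.input_shape):
        raise InvalidInputError(
            f"data shape {X.shape[-2:]} does not match model input "
            f"{model.model_config.input_shape}"
        )


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def train(
    model: TrainedModel,
    split: DatasetSplit,
    tcfg: TrainingConfig,
    on_epoch_end=None,
) -> TrainedModel:
    """SGD-with-momentum training; cross-entropy loss.

    ``error_curve[e]`` is the percentage of training exemplars misclassified
    during epoch ``e`` (accumulated over minibatches as the parameters move).
    ``on_epoch_end(epoch, model)`` runs after each epoch, e.g. to checkpoint
    or to measure epoch-wise representation geometry.
    """
    X, y = _stack(split.train)
    _check_shape(model, X)
    n = len(y)
    net = model.network
    rng = np.random.default_rng(tcfg.seed)
    params = net.params()
    model.training_config = tcfg
    model.error_curve = []
    for epoch in range(tcfg.epochs):
        perm = rng.permutation(n)
        n_wrong = 0
        for start in range(0, n, tcfg.batch_size):
            sel = perm[start : start + tcfg.batch_size]
            xb, yb = X[sel], y[sel]
            scores = net.forward(xb, train=True)
            probs = _softmax(scores)
            n_wrong += int(np.sum(scores.argmax(axis=1) != yb))
            g = probs
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            for p in params:
                p.grad[...] = 0.0
            net.backward(g)
            for p in params:
                p.mom = tcfg.momentum * p.mom - tcfg.learning_rate * p.grad
                p.value += p.mom
        model.error_curve.append(100.0 * n_wrong / n)
        if on_epoch_end is not None:
            on_epoch_end(epoch, model)
    return model


def predict_batch(model: TrainedModel, samples: list[MelSpectrogram]) -> np.ndarray:
    """Probability matrix (n_samples, n_classes)."""
    X, _ = _stack(samples)
    _check_shape(model, X)
    out = []
    for start in range(0, len(samples), 64):
        out.append(_softmax(model.network.forward(X[start : start + 64], train=False)))
    return np.concatenate(out)


def predict(model: TrainedModel, spec: MelSpectrogram) -> PredictiveDistribution:
    """Probability distribution over the lexicon for one spectrogram."""
    return PredictiveDistribution(probs=predict_batch(model, [spec])[0])


def extract_activations(
    model: TrainedModel, samples: list[MelSpectrogram], layer_ids: list[str]
) -> ActivationSet:
    """Flattened post-nonlinearity feature vectors per layer, grouped by class."""
    registry = model.model_config.conv_layer_registry
    unknown = [l for l in layer_ids if l not in registry]
    if unknown:
        raise ConfigurationError(f"unknown layer ids {unknown}; registry: {registry}")
    X, y = _stack(samples)
    _check_shape(model, X)
    feats: dict[str, list[np.ndarray]] = {l: [] for l in layer_ids}
    for start in range(0, len(samples), 64):
        taps = {l: None for l in layer_ids}
        model.network.forward(X[start : start + 64], train=False, taps=taps)
        for l in layer_ids:
            feats[l].append(taps[l].reshape(taps[l].shape[0], -1))
    class_ids = sorted(set(int(v) for v in y))
    layers = {}
    for l in layer_ids:
        all_feats = np.concatenate(feats[l])
        layers[l] = [all_feats[y == c] for c in class_ids]
    return ActivationSet(layers=layers, class_ids=class_ids)
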