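"""A compact NumPy convolutional-network engine for AIO classification.

The images are tiny (6 × ~40 × 3), so convolution, pooling and dense layers
with explicit forward/backward passes in NumPy train in seconds on one CPU;
the engine also exposes exactly what the explanation methods need
(gradients with respect to the input for saliency maps, intermediate
convolution activations for Score-CAM).

Architectures are declarative (:class:`ArchSpec`): a sequence of
2-D convolution (3×3 kernel, shape-preserving "same" padding, stride 1),
2×2 max pooling with floor semantics (an odd trailing row/column is
dropped: height 6 → 3 → 1), optional per-channel batch normalization,
flatten, and dense layers. The final dense layer has one unit per
flowering-time class; the loss is categorical cross-entropy on its softmax,
L = −Σ_i T_i log S_i with T the one-hot truth and S the predicted
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np


@dataclass
class ArchSpec:
    """Declarative architecture: input shape (height, width, channels) and an
    ordered list of layer descriptors.

    Layer descriptors (dicts):
      {"type": "conv", "filters": F, "kernel": [kh, kw], "activation": "relu",
       "batchnorm": false}
      {"type": "pool", "size": [ph, pw]}
      {"type": "flatten"}
      {"type": "dense", "units": U, "activation": "relu"}  # last layer: "softmax"
    """

    input_shape: tuple
    layers: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.input_shape = tuple(self.input_shape)
        if len(self.input_shape) not in (1, 3):
            raise ValueError("input_shape must be (height, width, channels) or (features,)")
        if not self.layers:
            raise ValueError("architecture needs at least one layer")
        last = self.layers[-1]
        if last["type"] != "dense":
            raise ValueError("final layer must be dense (one unit per class)")
        if last["units"] < 2:
            raise ValueError("need at least 2 output classes")

    @property
    def n_classes(self) -> int:
        return self.layers[-1]["units"]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"input_shape": list(self.input_shape),
                                          "layers": self.layers}))

    @classmethod
    def from_json(cls, path) -> "ArchSpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["input_shape"]), d["layers"])


def union_set_architecture(width: int = 40, n_classes: int = 15) -> ArchSpec:
    """The tuned 7-layer architecture for 90-SNP (union-set) AIOs:
    conv(10) → pool → conv(50) → pool → flatten → dense(45) → dense(classes).
    At width 40 the trainable parameter counts are 280 / 4550 / 22545 / 690
    (28,065 total)."""
    return ArchSpec((6, width, 3), [
        {"type": "conv", "filters": 10, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "conv", "filters": 50, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "flatten"},
        {"type": "dense", "units": 45, "activation": "relu"},
        {"type": "dense", "units": n_classes, "activation": "softmax"},
    ])


def cross_set_architecture(width: int = 28, n_classes: int = 15) -> ArchSpec:
    """The tuned 7-layer architecture for 17-SNP (cross-set) AIOs:
    conv(7) → pool → conv(42) → pool → flatten → dense(45) → dense(classes).
    At width 28 the trainable parameter counts are 196 / 2688 / 13275 / 690."""
    return ArchSpec((6, width, 3), [
        {"type": "conv", "filters": 7, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "conv", "filters": 42, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "flatten"},
        {"type": "dense", "units": 45, "activation": "relu"},
        {"type": "dense", "units": n_classes, "activation": "softmax"},
    ])


def count_params(arch: ArchSpec):
    """Per-layer and total trainable parameter counts.

    Convolution: kh·kw·in_channels·filters + filters; dense: in·units +
    units; batch normalization: 2·channels (scale and shift); pooling and
    flatten: 0. Raises on shape inconsistencies (e.g. pooling a dimension
    to zero, dense before flatten).
    """
    shape = arch.input_shape
    counts = []
    for li, layer in enumerate(arch.layers):
        t = layer["type"]
        if t == "conv":
            if len(shape) != 3:
                raise ValueError(f"layer {li}: convolution needs a 3-D input, got {shape}")
            h, w, c = shape
            kh, kw = layer.get("kernel", [3, 3])
            f = layer["filters"]
            if f < 1:
                raise ValueError(f"layer {li}: filters must be ≥ 1")
            n = kh * kw * c * f + f
            if layer.get("batchnorm"):
                n += 2 * f
            counts.append(n)
            shape = (h, w, f)
        elif t == "pool":
            if len(shape) != 3:
                raise ValueError(f"layer {li}: pooling needs a 3-D input, got {shape}")
            h, w, c = shape
            ph, pw = layer.get("size", [2, 2])
            nh, nw = h // ph, w // pw
            if nh < 1 or nw < 1:
                raise ValueError(f"layer {li}: pooling {shape} by {ph}×{pw} empties the map")
            counts.append(0)
            shape = (nh, nw, c)
        elif t == "flatten":
            counts.append(0)
            shape = (int(np.prod(shape)),)
        elif t == "dense":
            if len(shape) != 1:
                raise ValueError(f"layer {li}: dense needs a flat input, got {shape}")
            u = layer["units"]
            counts.append(shape[0] * u + u)
            shape = (u,)
        else:
            raise ValueError(f"layer {li}: unknown type {t!r}")
    return counts, int(sum(counts))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


class Conv2D:
    """3×3 (configurable) convolution, stride 1, same padding, via im2col."""

    def __init__(self, in_shape, filters, kernel=(3, 3), activation="relu", rng=None):
        h, w, c = in_shape
        kh, kw = kernel
        self.kh, self.kw, self.c, self.f = kh, kw, c, filters
        self.activation = activation
        scale = np.sqrt(2.0 / (kh * kw * c))
        self.W = rng.normal(0.0, scale, (kh * kw * c, filters))
        self.b = np.zeros(filters)
        self.out_shape = (h, w, filters)

    @property
    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        n, h, w, c = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, (n, h, w, self.kh, self.kw, c),
            (s[0], s[1], s[2], s[1], s[2], s[3]), writeable=False)
        return view.reshape(n * h * w, self.kh * self.kw * c)

    def forward(self, x, training=False):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        n, h, w, _ = x.shape
        z = (self.cols @ self.W + self.b).reshape(n, h, w, self.f)
        self.z = z
        if self.activation == "relu":
            return _relu(z)
        if self.activation == "tanh":
            return np.tanh(z)
        if self.activation == "linear":
            return z
        raise ValueError(f"unknown activation {self.activation!r}")

    def backward(self, dout):
        if self.activation == "relu":
            dz = dout * (self.z > 0)
        elif self.activation == "tanh":
            dz = dout * (1.0 - np.tanh(self.z) ** 2)
        else:
            dz = dout
        n, h, w, c = self.x_shape
        dzf = dz.reshape(n * h * w, self.f)
        self.dW = self.cols.T @ dzf
        self.db = dzf.sum(axis=0)
        dcols = (dzf @ self.W.T).reshape(n, h, w, self.kh, self.kw, c)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, ph:ph + h, pw:pw + w, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, in_shape, momentum=0.9):
        c = in_shape[-1]
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = 1e-5
        self.out_shape = in_shape

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.std = np.sqrt(var + self.eps)
        self.xhat = (x - mean) / self.std
        self.training = training
        self.n = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self.xhat + self.beta

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.dgamma = (dout * self.xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        if not self.training:
            return dout * self.gamma / self.std
        n = self.n
        dxhat = dout * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self.xhat * (dxhat * self.xhat).mean(axis=axes)) / self.std

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class MaxPool2D:
    """Non-overlapping max pooling with floor semantics: trailing rows or
    columns that do not fill a window are dropped (6→3→1 for 2×2)."""

    def __init__(self, in_shape, size=(2, 2)):
        h, w, c = in_shape
        self.ph, self.pw = size
        self.oh, self.ow = h // self.ph, w // self.pw
        if self.oh < 1 or self.ow < 1:
            raise ValueError(f"pooling {in_shape} by {size} empties the feature map")
        self.out_shape = (self.oh, self.ow, c)
        self.in_shape = in_shape

    params = []
    grads = []

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xc = x[:, : self.oh * self.ph, : self.ow * self.pw, :]
        win = xc.reshape(n, self.oh, self.ph, self.ow, self.pw, c)
        win = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, self.oh, self.ow, c, self.ph * self.pw)
        self.arg = win.argmax(axis=-1)
        self.x_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self.x_shape
        dwin = np.zeros((n, self.oh, self.ow, c, self.ph * self.pw))
        np.put_along_axis(dwin, self.arg[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(n, self.oh, self.ow, c, self.ph, self.pw)
        dxc = dxc.transpose(0, 1, 4, 2, 5, 3).reshape(n, self.oh * self.ph, self.ow * self.pw, c)
        dx = np.zeros((n, h, w, c))
        dx[:, : self.oh * self.ph, : self.ow * self.pw, :] = dxc
        return dx


class Flatten:
    def __init__(self, in_shape):
        self.in_shape = in_shape
        self.out_shape = (int(np.prod(in_shape)),)

    params = []
    grads = []

    def forward(self, x, training=False):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.x_shape)


class Dense:
    def __init__(self, in_shape, units, activation="relu", rng=None):
        d = in_shape[0]
        self.W = rng.normal(0.0, np.sqrt(2.0 / d), (d, units))
        self.b = np.zeros(units)
        self.activation = activation
        self.out_shape = (units,)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self.x = x
        self.z = x @ self.W + self.b
        if self.activation == "relu":
            return _relu(self.z)
        if self.activation == "tanh":
            return np.tanh(self.z)
        # "softmax"/"linear": return logits; softmax applied by the loss
        return self.z

    def backward(self, dout):
        if self.activation == "relu":
            dz = dout * (self.z > 0)
        elif self.activation == "tanh":
            dz = dout * (1.0 - np.tanh(self.z) ** 2)
        else:
            dz = dout
        self.dW = self.x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """Sequential network built from an :class:`ArchSpec`.

    ``forward`` returns logits; ``predict_proba`` their softmax;
    ``input_gradient`` backpropagates a class logit to the input image
    (used by saliency maps); ``conv_activations`` captures the outputs of
    convolution layers (used by Score-CAM).
    """

    def __init__(self, arch: ArchSpec, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.layers = []
        self.conv_indices = []
        shape = arch.input_shape
        for spec in arch.layers:
            t = spec["type"]
            if t == "conv":
                layer = Conv2D(shape, spec["filters"], tuple(spec.get("kernel", (3, 3))),
                               spec.get("activation", "relu"), rng=rng)
                self.conv_indices.append(len(self.layers))
                self.layers.append(layer)
                shape = layer.out_shape
                if spec.get("batchnorm"):
                    bn = BatchNorm(shape)
                    self.layers.append(bn)
            elif t == "pool":
                layer = MaxPool2D(shape, tuple(spec.get("size", (2, 2))))
                self.layers.append(layer)
                shape = layer.out_shape
            elif t == "flatten":
                layer = Flatten(shape)
                self.layers.append(layer)
                shape = layer.out_shape
            elif t == "dense":
                layer = Dense(shape, spec["units"], spec.get("activation", "relu"), rng=rng)
                self.layers.append(layer)
                shape = layer.out_shape
            else:
                raise ValueError(f"unknown layer type {t!r}")
        self.n_classes = arch.n_classes

    # -- inference ---------------------------------------------------------
    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x):
        return self._softmax(self.forward(np.asarray(x, dtype=float)))

    def predict(self, x):
        return self.forward(np.asarray(x, dtype=float)).argmax(axis=1)

    # -- training ----------------------------------------------------------
    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def loss_and_backward(self, x, y_onehot):
        """Mean categorical cross-entropy over the batch; fills layer grads."""
        logits = self.forward(x, training=True)
        probs = self._softmax(logits)
        n = x.shape[0]
        loss = -np.sum(y_onehot * np.log(np.clip(probs, 1e-12, None))) / n
        dlogits = (probs - y_onehot) / n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    # -- explanation hooks -------------------------------------------------
    def input_gradient(self, x, target_class: int):
        """∂ logit[target_class] / ∂ x for a batch of images."""
        if not 0 <= target_class < self.n_classes:
            raise ValueError(f"target_class {target_class} out of range")
        logits = self.forward(np.asarray(x, dtype=float), training=False)
        seed_grad = np.zeros_like(logits)
        seed_grad[:, target_class] = 1.0
        grad = seed_grad
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def conv_activations(self, x):
        """Outputs of every convolution layer for a batch."""
        acts = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training=False)
            if i in self.conv_indices:
                acts.append(x)
        return acts

    # -- persistence -------------------------------------------------------
    def save_weights(self, path):
        np.savez(path, *self.params)

    def load_weights(self, path):
        data = np.load(path)
        for p, key in zip(self.params, data.files):
            p[:] = data[key]


def build_model(arch: ArchSpec, seed: int = 0) -> Network:
    """Instantiate a trainable network; its parameter count matches
    :func:`count_params` exactly."""
    net = Network(arch, seed=seed)
    _, total = count_params(arch)
    assert net.n_params() == total, "parameter count mismatch between spec and network"
    return net
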