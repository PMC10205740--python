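"""Minimal CPU neural-network stack used by the damage models.

Implements exactly the pieces the segmentation and regression models need:
3x3/1x1 convolutions, batch normalization, ReLU, 2x2 max-pooling, nearest
up-sampling, global pooling heads, dense layers, dropout, a U-Net
encoder/decoder and a VGG-style backbone, together with explicit backward
passes and the Adamax optimizer.  Arrays are NHWC, float32 by default.

Everything is deterministic given the construction seed: weight
initialization, dropout masks and (through the callers) batch sampling all
derive from `numpy.random.Generator` instances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "UpSample2",
    "GlobalMaxPool",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "ConvBlock",
    "UNet",
    "VGGRegressor",
    "Adamax",
    "softmax",
    "sigmoid",
    "softmax_cross_entropy",
    "sigmoid_bce",
    "sigmoid_regression_loss",
]


class Parameter:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("w", "g")

    def __init__(self, w: np.ndarray):
        self.w = w
        self.g = np.zeros_like(w)


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """`same`-padded convolution, kernel 3x3 or 1x1, bias included."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, *, rng=None, dtype=np.float32):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = ksize
        self.cin, self.cout = cin, cout
        self.W = Parameter(_he_normal(rng, (ksize, ksize, cin, cout), ksize * ksize * cin, dtype))
        self.b = Parameter(np.zeros(cout, dtype))
        self._xp = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        N, H, W, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp if train else None
        y = np.empty((N, H, W, self.cout), x.dtype)
        y[...] = self.b.w
        for di in range(k):
            for dj in range(k):
                y += xp[:, di:di + H, dj:dj + W, :] @ self.W.w[di, dj]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._xp
        N, H, W, _ = gy.shape
        self.b.g += gy.sum(axis=(0, 1, 2))
        gy2 = gy.reshape(-1, self.cout)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + H, dj:dj + W, :].reshape(-1, self.cin)
                self.W.g[di, dj] += xs.T @ gy2
                gxp[:, di:di + H, dj:dj + W, :] += gy @ self.W.w[di, dj].T
        self._xp = None
        return gxp[:, p:p + H, p:p + W, :] if p else gxp


class BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, *, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype))
        self.beta = Parameter(np.zeros(channels, dtype))
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(channels, dtype)
        self.run_var = np.ones(channels, dtype)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mean
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(x.dtype), axes)
        return self.gamma.w * xhat + self.beta.w

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        self._cache = None
        n = gy.size // gy.shape[-1]
        self.gamma.g += (gy * xhat).sum(axis=axes)
        self.beta.g += gy.sum(axis=axes)
        gxhat = gy * self.gamma.w
        gx = inv * (gxhat - gxhat.mean(axis=axes) - xhat * (gxhat * xhat).sum(axis=axes) / n)
        return gx


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, train):
        mask = x > 0
        self._mask = mask if train else None
        return x * mask

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool2:
    """2x2 max-pooling with stride 2; odd spatial dims are replicate-padded."""

    def __init__(self):
        self._arg = None
        self._shape = None
        self._orig = None

    def parameters(self):
        return []

    @staticmethod
    def _windows(x):
        N, H, W, C = x.shape
        return x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(
            N, H // 2, W // 2, 4, C)

    def forward(self, x, train):
        orig = x.shape
        if x.shape[1] % 2:
            x = np.concatenate([x, x[:, -1:]], axis=1)
        if x.shape[2] % 2:
            x = np.concatenate([x, x[:, :, -1:]], axis=2)
        xw = self._windows(x)
        arg = xw.argmax(axis=3)
        if train:
            self._arg, self._shape, self._orig = arg, x.shape, orig
        return np.take_along_axis(xw, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, gy):
        N, H, W, C = self._shape
        gw = np.zeros((N, H // 2, W // 2, 4, C), gy.dtype)
        np.put_along_axis(gw, self._arg[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        gx = gw.reshape(N, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(
            N, H, W, C)
        _, Ho, Wo, _ = self._orig
        if H != Ho:
            gx[:, Ho - 1] += gx[:, Ho]
            gx = gx[:, :Ho]
        if W != Wo:
            gx[:, :, Wo - 1] += gx[:, :, Wo]
            gx = gx[:, :, :Wo]
        self._arg = self._shape = self._orig = None
        return gx


class UpSample2:
    """Nearest-neighbour 2x up-sampling."""

    def parameters(self):
        return []

    def forward(self, x, train):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy):
        N, H, W, C = gy.shape
        return gy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class GlobalMaxPool:
    def __init__(self):
        self._arg = None
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x, train):
        N, H, W, C = x.shape
        xf = x.reshape(N, H * W, C)
        arg = xf.argmax(axis=1)
        if train:
            self._arg, self._shape = arg, x.shape
        return np.take_along_axis(xf, arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, gy):
        N, H, W, C = self._shape
        gf = np.zeros((N, H * W, C), gy.dtype)
        np.put_along_axis(gf, self._arg[:, None, :], gy[:, None, :], axis=1)
        self._arg = self._shape = None
        return gf.reshape(N, H, W, C)


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy):
        N, H, W, C = self._shape
        self._shape = None
        return np.broadcast_to(gy[:, None, None, :] / (H * W), (N, H, W, C)).astype(gy.dtype)


class Dense:
    def __init__(self, fin: int, fout: int, *, rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Parameter(_he_normal(rng, (fin, fout), fin, dtype))
        self.b = Parameter(np.zeros(fout, dtype))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W.w + self.b.w

    def backward(self, gy):
        self.W.g += self._x.T @ gy
        self.b.g += gy.sum(axis=0)
        gx = gy @ self.W.w.T
        self._x = None
        return gx


class Dropout:
    def __init__(self, rate: float, *, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


class ConvBlock(_Sequential):
    """conv-BN-ReLU twice: the per-level block of the U-Net family."""

    def __init__(self, cin: int, cout: int, *, rng, dtype=np.float32):
        super().__init__([
            Conv2D(cin, cout, 3, rng=rng, dtype=dtype),
            BatchNorm(cout, dtype=dtype),
            ReLU(),
            Conv2D(cout, cout, 3, rng=rng, dtype=dtype),
            BatchNorm(cout, dtype=dtype),
            ReLU(),
        ])


class UNet:
    """Encoder/decoder with skip connections and per-pixel output head.

    ``widths`` are the encoder block channel counts; the last entry is the
    bottleneck, so the network pools ``len(widths) - 1`` times.  The decoder
    mirrors the encoder; skips are concatenated after nearest up-sampling.
    ``out_channels`` is 3 (softmax classes) for the damage segmenter and 1
    (sigmoid logit) for the binary epidermis masker.
    """

    def __init__(self, widths=(16, 32, 64, 128), in_channels: int = 3,
                 out_channels: int = 3, *, seed: int = 0, dtype=np.float32):
        widths = tuple(int(w) for w in widths)
        if len(widths) < 2 or any(b <= a for a, b in zip(widths, widths[1:])):
            raise ValueError("widths must be strictly increasing, length >= 2")
        rng = np.random.default_rng(seed)
        self.widths = widths
        self.pool_count = len(widths) - 1
        self.out_channels = out_channels
        self.enc = []
        cin = in_channels
        for w in widths:
            self.enc.append(ConvBlock(cin, w, rng=rng, dtype=dtype))
            cin = w
        self.pools = [MaxPool2() for _ in range(self.pool_count)]
        self.ups = [UpSample2() for _ in range(self.pool_count)]
        self.dec = []
        for w_skip in reversed(widths[:-1]):
            self.dec.append(ConvBlock(cin + w_skip, w_skip, rng=rng, dtype=dtype))
            cin = w_skip
        self.head = Conv2D(cin, out_channels, 1, rng=rng, dtype=dtype)
        self._skip_channels = None

    def parameters(self):
        out = []
        for block in self.enc + self.dec:
            out.extend(block.parameters())
        out.extend(self.head.parameters())
        return out

    def num_parameters(self) -> int:
        return sum(p.w.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        side = 2 ** self.pool_count
        if x.shape[1] % side or x.shape[2] % side:
            raise ValueError(
                f"input spatial dims must be divisible by {side}, got {x.shape[1:3]}")
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, train)
            if i < self.pool_count:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i, block in enumerate(self.dec):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([skips.pop(), x], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gy: np.ndarray) -> None:
        gy = self.head.backward(gy)
        skip_grads = []
        for i in reversed(range(len(self.dec))):
            gy = self.dec[i].backward(gy)
            c = self._skip_channels[self.pool_count - 1 - i]
            skip_grads.append(gy[..., :c])
            gy = self.ups[i].backward(gy[..., c:])
        for i in reversed(range(len(self.enc))):
            if i < self.pool_count:
                gy = self.pools[i].backward(gy)
                gy = gy + skip_grads[i]
            gy = self.enc[i].backward(gy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax) or foreground probability (sigmoid)."""
        logits = self.forward(x, train=False)
        if self.out_channels == 1:
            return sigmoid(logits)
        return softmax(logits)


#: channel plan of the 13-convolution VGG16 feature extractor; "P" marks a 2x2 pool.
VGG16_PLAN = (64, 64, "P", 128, 128, "P", 256, 256, 256, "P",
              512, 512, 512, "P", 512, 512, 512, "P")


class VGGRegressor:
    """VGG16-style backbone with a pooled regression head.

    The feature extractor follows the 13-convolution VGG16 channel plan
    (batch-normalized so it trains from scratch on CPU); ``width_scale``
    shrinks every channel count proportionally for desk-scale experiments.
    The head concatenates global max- and mean-pooling of the final feature
    map (1024 = 512 + 512 at scale 1), applies dropout, a 128-unit ReLU
    layer, dropout again and a single sigmoid output neuron.
    """

    def __init__(self, *, width_scale: float = 1.0, head_hidden: int = 128,
                 dropout_rate: float = 0.5, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        layers = []
        cin = 3
        last = cin
        for item in VGG16_PLAN:
            if item == "P":
                layers.append(MaxPool2())
            else:
                cout = max(4, int(round(item * width_scale)))
                layers.append(Conv2D(cin, cout, 3, rng=rng, dtype=dtype))
                layers.append(BatchNorm(cout, dtype=dtype))
                layers.append(ReLU())
                cin = cout
                last = cout
        self.backbone = _Sequential(layers)
        self.gmp = GlobalMaxPool()
        self.gap = GlobalAvgPool()
        self.head_width = 2 * last
        self.drop1 = Dropout(dropout_rate, rng=rng)
        self.fc1 = Dense(self.head_width, head_hidden, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.drop2 = Dropout(dropout_rate, rng=rng)
        self.fc2 = Dense(head_hidden, 1, rng=rng, dtype=dtype)
        self._split = None

    def parameters(self):
        return (self.backbone.parameters() + self.fc1.parameters() + self.fc2.parameters())

    def num_parameters(self) -> int:
        return sum(p.w.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Returns the pre-sigmoid logit, shape (N,)."""
        f = self.backbone.forward(x, train)
        z = np.concatenate([self.gmp.forward(f, train), self.gap.forward(f, train)], axis=1)
        self._split = z.shape[1] // 2
        z = self.drop1.forward(z, train)
        z = self.relu.forward(self.fc1.forward(z, train), train)
        z = self.drop2.forward(z, train)
        return self.fc2.forward(z, train)[:, 0]

    def backward(self, glogit: np.ndarray) -> None:
        gy = self.fc2.backward(glogit[:, None])
        gy = self.drop2.backward(gy)
        gy = self.fc1.backward(self.relu.backward(gy))
        gy = self.drop1.backward(gy)
        s = self._split
        gf = self.gmp.backward(gy[:, :s]) + self.gap.backward(gy[:, s:])
        self.backbone.backward(gf)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Damage-score estimates in (0, 1)."""
        return sigmoid(self.forward(x, train=False))


# ---------------------------------------------------------------------------
# losses and optimizer
# ---------------------------------------------------------------------------


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype) if isinstance(z, np.ndarray) else out


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy over all positions; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.size // logits.shape[-1]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, ((p - onehot) / n).astype(logits.dtype)


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray):
    """Mean per-element binary cross-entropy on logits; returns (loss, dlogits)."""
    z, y = logits, targets
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    return loss, ((sigmoid(z) - y) / z.size).astype(logits.dtype)


def sigmoid_regression_loss(logits: np.ndarray, targets: np.ndarray, kind: str = "mse"):
    """MSE or MAE between sigmoid(logit) and target; returns (loss, dlogits)."""
    s = sigmoid(logits.astype(np.float64))
    err = s - targets
    if kind == "mse":
        loss = float(np.mean(err ** 2))
        g = 2.0 * err * s * (1.0 - s) / err.size
    elif kind == "mae":
        loss = float(np.mean(np.abs(err)))
        g = np.sign(err) * s * (1.0 - s) / err.size
    else:
        raise ValueError(f"unknown regression loss {kind!r}")
    return loss, g.astype(logits.dtype)


class Adamax:
    """Adamax (infinity-norm Adam variant): lr 0.001, beta1 0.9, beta2 0.999, eps 1e-7."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.w) for p in self.params]
        self.u = [np.zeros_like(p.w) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0

    def step(self):
        self.t += 1
        corr = 1.0 - self.b1 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            np.maximum(self.b2 * u, np.abs(p.g), out=u)
            p.w -= (self.lr / corr) * m / (u + self.eps)
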