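"""Small convolutional network in plain numpy.

Forward/backward passes are expressed as batched GEMMs over im2col patches,
which keeps training of the ~100k-parameter "tiny-scratch" network on 64x64
RGB inputs fast enough for a single CPU. The input gradient of a
convolution is computed as a full correlation of the output gradient with
the 180-degree-rotated kernels (another im2col GEMM) rather than a
scatter-add, for the same reason.

The optimizer is Adam with decoupled weight decay (applied to weight
matrices only); the learning-rate policy is one cycle over the whole run —
linear warmup to the peak, then cosine annealing. Everything is driven by
seeded Generators, so training is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TinyConvNet"]


def _shift2d(img: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Translate along one axis with zero fill (no wrap-around)."""
    if d == 0:
        return img
    out = np.roll(img, d, axis=axis)
    sl = [slice(None)] * img.ndim
    sl[axis] = slice(0, d) if d > 0 else slice(d, None)
    out[tuple(sl)] = 0
    return out


def _random_shift(images: np.ndarray, rng: np.random.Generator, max_t: int, max_f: int) -> np.ndarray:
    """Random translation of (H=frequency, W=time, 3) images, applied to
    roughly half of the batch so the clean views are still seen."""
    out = images.copy()
    apply = rng.uniform(size=len(images)) < 0.5
    dts = rng.integers(-max_t, max_t + 1, size=len(images))
    dfs = rng.integers(-max_f, max_f + 1, size=len(images))
    for i in np.flatnonzero(apply):
        out[i] = _shift2d(_shift2d(out[i], dts[i], 1), dfs[i], 0)
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of a 3x3/pad-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, 3, 3, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return windows.reshape(n, c * 9, h * w)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init for ReLU stacks
        self.w = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._col = _im2col(x)
        n, _, hw = self._col.shape
        out = np.matmul(self.w, self._col) + self.b[None, :, None]
        h = self._shape[2]
        return out.reshape(n, self.c_out, h, self._shape[3])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = dy.shape
        dyf = dy.reshape(n, self.c_out, h * w)
        self.dw = np.matmul(dyf, self._col.transpose(0, 2, 1)).sum(axis=0)
        self.db = dyf.sum(axis=(0, 2))
        # dx = full-correlation of dy with rotated kernels
        w_rot = (
            self.w.reshape(self.c_out, self.c_in, 3, 3)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.c_in, self.c_out * 9)
        )
        col_dy = _im2col(dy)
        dx = np.matmul(w_rot, col_dy)
        return dx.reshape(self._shape)

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _BatchNorm:
    """Per-channel batch normalization for (N, C, H, W) maps."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        self.dgamma = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        return dx

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x):
        self._in_shape = x.shape
        self._x = x.reshape(x.shape[0], -1)
        return self._x @ self.w.T + self.b

    def backward(self, dy):
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return (dy @ self.w).reshape(self._in_shape)

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


@dataclass
class TinyConvNet:
    """3 conv blocks (16/32/64 channels, each 3x3 conv + batch norm + ReLU +
    2x2 maxpool) and a linear head. Input: (N, 64, 64, 3) images in [0, 1]
    (uint8 accepted). ~100k parameters.
    """

    n_classes: int
    input_size: int = 64
    seed: int = 0
    channels: tuple[int, int, int] = (16, 32, 64)
    history: list[float] = field(default_factory=list)  # per-epoch mean loss

    def __post_init__(self) -> None:
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        rng = np.random.default_rng(self.seed)
        c1, c2, c3 = self.channels
        d = (self.input_size // 8) ** 2 * c3
        self.layers = [
            _Conv3x3(3, c1, rng), _BatchNorm(c1), _ReLU(), _MaxPool2(),
            _Conv3x3(c1, c2, rng), _BatchNorm(c2), _ReLU(), _MaxPool2(),
            _Conv3x3(c2, c3, rng), _BatchNorm(c3), _ReLU(), _MaxPool2(),
            _Dense(d, self.n_classes, rng),
        ]

    def _set_training(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.training = flag

    # ---- forward / loss ---------------------------------------------------

    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.max() > 1.5:  # uint8 input
            x = x / np.float32(255.0)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2)) - np.float32(0.5)

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        self._set_training(False)
        return self._forward(self._prep(images))

    def predict_proba(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch):
            logits = self.predict_logits(images[i : i + batch])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    # ---- training ---------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 15,
        batch_size: int = 128,
        lr_peak: float = 0.003,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 0.01,
        augment_shift: tuple[int, int] | None = None,
    ) -> "TinyConvNet":
        """Train with cross-entropy; ``augment_shift`` = (max time px, max
        frequency px) random zero-filled translation applied to half of each
        batch (None, the default, disables augmentation)."""
        labels = np.asarray(labels)
        n = len(labels)
        if batch_size > n:
            warnings.warn(f"batch size {batch_size} exceeds dataset size {n}; clamping")
            batch_size = n
        rng = np.random.default_rng(self.seed + 1)
        self._set_training(True)
        params = [(layer, name, grad) for layer in self.layers for name, _, grad in layer.params()]
        m = [np.zeros_like(getattr(layer, name)) for layer, name, _ in params]
        v = [np.zeros_like(getattr(layer, name)) for layer, name, _ in params]
        step = 0
        n_batches = max(1, int(np.ceil(n / batch_size)))
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for bi in range(n_batches):
                idx = order[bi * batch_size : (bi + 1) * batch_size]
                batch = images[idx]
                if augment_shift is not None:
                    batch = _random_shift(batch, rng, *augment_shift)
                x = self._prep(batch)
                y = labels[idx]
                logits = self._forward(x)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                p = e / e.sum(axis=1, keepdims=True)
                losses.append(float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))))
                dy = p.copy()
                dy[np.arange(len(y)), y] -= 1.0
                dy /= len(y)  # mean loss; layers accumulate raw sums
                for layer in reversed(self.layers):
                    dy = layer.backward(dy)
                # one cycle over the whole run: linear warmup to the peak,
                # then cosine annealing to ~0 (the policy the cyclical-LR
                # practice converged on for short fine-tuning runs)
                phase = (epoch * n_batches + bi + 0.5) / (epochs * n_batches)
                if phase < 0.45:
                    lr = lr_peak / 25.0 + (lr_peak - lr_peak / 25.0) * (phase / 0.45)
                else:
                    t = (phase - 0.45) / 0.55
                    lr = lr_peak * (1e-4 + (1 - 1e-4) * 0.5 * (1 + np.cos(np.pi * t)))
                step += 1
                for j, (layer, name, gname) in enumerate(params):
                    g = getattr(layer, gname)
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1**step)
                    vhat = v[j] / (1 - beta2**step)
                    p_arr = getattr(layer, name)
                    # decoupled decay on weight matrices only (not biases/BN)
                    wd = weight_decay if name == "w" else 0.0
                    p_arr -= lr * (mhat / (np.sqrt(vhat) + 1e-8) + wd * p_arr)
            self.history.append(float(np.mean(losses)))
        self._set_training(False)
        return self
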