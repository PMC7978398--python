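"""Minimal NumPy neural-network engine for 1D residual convolutional nets.

Implements exactly what the package needs: 'same'-padded strided 1D
convolutions (im2col), ReLU with an optional guided-backprop backward pass,
global average pooling, a dense head, Glorot-uniform initialization, and
Adam. Forward passes cache activations so a single ``backward`` call yields
both parameter gradients and the gradient with respect to the input signal —
the hook every attribution method in :mod:`ppgxai.saliency` relies on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ResNet1d", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1d:
    """'same'-padded 1D convolution (cross-correlation) with stride."""

    def __init__(self, cin, cout, k, stride, rng):
        self.k, self.stride = k, stride
        self.W = _glorot_uniform(rng, (cout, cin, k), cin * k, cout * k)
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def out_len(self, L):
        return -(-L // self.stride)  # ceil

    def _padding(self, L):
        Lo = self.out_len(L)
        total = max((Lo - 1) * self.stride + self.k - L, 0)
        return total // 2, total - total // 2

    def forward(self, x):
        self._L = x.shape[2]
        left, right = self._padding(self._L)
        self._left = left
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        self._Lp = xp.shape[2]
        win = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.stride, :]
        self._win = win
        y = np.tensordot(win, self.W, axes=([1, 3], [1, 2]))  # (B, Lo, Cout)
        return y.transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, gy, accumulate_params=True):
        win = self._win
        if accumulate_params:
            self.gW += np.tensordot(gy, win, axes=([0, 2], [0, 2]))
            self.gb += gy.sum(axis=(0, 2))
        # (B, Lo, Cin, k) -> (B, Cin, Lo, k)
        gcol = np.tensordot(gy, self.W, axes=([1], [0])).transpose(0, 2, 1, 3)
        B, C = gcol.shape[0], gcol.shape[1]
        Lo = gy.shape[2]
        gxp = np.zeros((B, C, self._Lp))
        for t in range(self.k):
            gxp[:, :, t : t + (Lo - 1) * self.stride + 1 : self.stride] += gcol[
                :, :, :, t
            ]
        self._win = None
        return gxp[:, :, self._left : self._left + self._L]

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy, guided=False):
        gx = np.where(self._mask, gy, 0.0)
        if guided:
            gx = np.where(gx > 0, gx, 0.0)
        self._mask = None
        return gx

    params: list = []


class Tanh:
    """Saturating alternative used only to exercise the guided-backprop
    unsupported-model contract."""

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy, guided=False):
        gx = gy * (1.0 - self._y**2)
        self._y = None
        return gx

    params: list = []


class _Block:
    """Residual block: act(conv2(act(conv1(x))) + proj(x)).

    ``proj`` is a 1x1 convolution matching stride/channels of the main path;
    with all conv weights zeroed and an identity projection the block reduces
    to the identity map, which is the skip-connection contract."""

    def __init__(self, cin, cout, k, stride, rng, act_cls):
        self.conv1 = Conv1d(cin, cout, k, stride, rng)
        self.act1 = act_cls()
        self.conv2 = Conv1d(cout, cout, k, 1, rng)
        self.act2 = act_cls()
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv1d(cin, cout, 1, stride, rng)

    def forward(self, x):
        h = self.act1.forward(self.conv1.forward(x))
        h = self.conv2.forward(h)
        s = self.proj.forward(x) if self.proj is not None else x
        return self.act2.forward(h + s)

    def backward(self, gy, guided=False, accumulate_params=True):
        g = self.act2.backward(gy, guided=guided)
        gx_skip = self.proj.backward(g, accumulate_params) if self.proj is not None else g
        gh = self.conv2.backward(g, accumulate_params)
        gh = self.act1.backward(gh, guided=guided)
        gx_main = self.conv1.backward(gh, accumulate_params)
        return gx_main + gx_skip

    @property
    def params(self):
        out = self.conv1.params + self.conv2.params
        if self.proj is not None:
            out += self.proj.params
        return out


class ResNet1d:
    """Reduced 1D residual CNN with a scalar sigmoid output.

    Stem convolution (stride 4) -> ``depth`` residual blocks (each halving
    the length) -> global average pooling -> dense logit -> sigmoid.
    """

    def __init__(
        self,
        n_input: int,
        depth: int = 2,
        kernel_size: int = 80,
        channels: int = 8,
        seed: int = 0,
        activation: str = "relu",
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if kernel_size > n_input:
            raise ValueError(
                f"kernel size {kernel_size} exceeds input length {n_input}"
            )
        self.n_input = n_input
        self.depth = depth
        self.kernel_size = kernel_size
        self.channels = channels
        self.seed = seed
        self.activation = activation
        act_cls = {"relu": ReLU, "tanh": Tanh}[activation]
        rng = np.random.default_rng(seed)
        self.stem = Conv1d(1, channels, kernel_size, 4, rng)
        self.stem_act = act_cls()
        self.blocks = [
            _Block(channels, channels, kernel_size, 2, rng, act_cls)
            for _ in range(depth)
        ]
        # dense head on pooled channels
        self.Wd = _glorot_uniform(rng, (channels,), channels, 1)
        self.bd = 0.0
        self.gWd = np.zeros_like(self.Wd)
        self.gbd = 0.0

    # -- forward / backward ------------------------------------------------
    def logits(self, X: np.ndarray) -> np.ndarray:
        """Forward pass. ``X`` is (B, n); returns logits of shape (B,)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        h = self.stem_act.forward(self.stem.forward(X[:, None, :]))
        for blk in self.blocks:
            h = blk.forward(h)
        self._pool_len = h.shape[2]
        self._pooled = h.mean(axis=2)  # (B, C)
        return self._pooled @ self.Wd + self.bd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (artifact-free) class, shape (B,)."""
        return sigmoid(self.logits(X))

    def backward(self, gz: np.ndarray, guided: bool = False,
                 accumulate_params: bool = True) -> np.ndarray:
        """Backpropagate ``d loss / d logit`` (shape (B,)) down to the input.

        Returns the input gradient of shape (B, n). With ``guided=True``
        every ReLU additionally zeroes negative incoming backward signal."""
        gz = np.asarray(gz, dtype=float)
        if accumulate_params:
            self.gWd += self._pooled.T @ gz
            self.gbd += gz.sum()
        gp = gz[:, None] * self.Wd[None, :]  # (B, C)
        gh = np.repeat(gp[:, :, None], self._pool_len, axis=2) / self._pool_len
        for blk in reversed(self.blocks):
            gh = blk.backward(gh, guided=guided, accumulate_params=accumulate_params)
        gh = self.stem_act.backward(gh, guided=guided)
        gx = self.stem.backward(gh, accumulate_params)
        return gx[:, 0, :]

    def input_gradient(self, X: np.ndarray, guided: bool = False) -> np.ndarray:
        """Gradient of the output probability with respect to each input
        sample, shape (B, n)."""
        z = self.logits(X)
        p = sigmoid(z)
        return self.backward(p * (1.0 - p), guided=guided, accumulate_params=False)

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self):
        out = self.stem.params
        for blk in self.blocks:
            out += blk.params
        return out

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
        self.gWd[...] = 0.0
        self.gbd = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params] + [self.Wd.copy(), np.array(self.bd)]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w
        self.Wd[...] = weights[-2]
        self.bd = float(weights[-1])

    def get_config(self) -> dict:
        return {
            "n_input": self.n_input,
            "depth": self.depth,
            "kernel_size": self.kernel_size,
            "channels": self.channels,
            "seed": self.seed,
            "activation": self.activation,
        }


class Adam:
    """Adam over a model's (parameter, gradient) pairs, plus the dense head."""

    def __init__(self, model: ResNet1d, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        n = len(model.params)
        self.m = [np.zeros_like(p) for p, _ in model.params] + [
            np.zeros_like(model.Wd),
            0.0,
        ]
        self.v = [np.zeros_like(p) for p, _ in model.params] + [
            np.zeros_like(model.Wd),
            0.0,
        ]
        self._n = n

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        pairs = self.model.params + [
            (self.model.Wd, self.model.gWd),
        ]
        for i, (p, g) in enumerate(pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
        # scalar bias of the dense head
        i = self._n + 1
        g = self.model.gbd
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
        self.model.bd -= self.lr * (self.m[i] / b1t) / (
            np.sqrt(self.v[i] / b2t) + self.eps
        )
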