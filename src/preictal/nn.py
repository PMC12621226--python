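"""A compact numpy neural-network engine for the dual-branch classifier.

Implements exactly the layer vocabulary the architecture needs — valid 2D
convolution, batch normalization, max pooling with stride equal to the pool
size, LeakyReLU, bidirectional LSTM, and fully-connected layers — each with
a hand-written backward pass, plus cross-entropy loss, an Adam optimizer
with L2 weight decay, and a reduce-on-plateau learning-rate scheduler.
Every backward pass is verified against numerical differentiation in the
test suite.

Layers follow a minimal protocol: ``forward(x, training)`` caches what the
backward pass needs, ``backward(grad_out)`` returns the input gradient and
fills ``layer.grads`` (keyed like ``layer.params``).
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2d",
    "LeakyReLU",
    "Linear",
    "BiLSTM",
    "DualBranchNet",
    "cross_entropy",
    "Adam",
    "ReduceLROnPlateau",
]


class Layer:
    """Base layer: parameter/gradient dicts plus the forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: tuple = ()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv2d(Layer):
    """Unpadded (valid) 2D convolution with stride 1."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = (kh, kw)
        self.params["W"] = (rng.standard_normal((out_channels, in_channels, kh, kw))
                            * scale).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        kh, kw = self.kernel
        B, C, H, Wd = x.shape
        Ho, Wo = H - kh + 1, Wd - kw + 1
        if Ho <= 0 or Wo <= 0:
            raise ValueError(f"input {H}x{Wd} too small for {kh}x{kw} kernel")
        y = np.zeros((B, W.shape[0], Ho, Wo), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                y += np.einsum("bchw,oc->bohw", x[:, :, i:i + Ho, j:j + Wo],
                               W[:, :, i, j], optimize=True)
        y += b[None, :, None, None]
        self._cache = (x,)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        W = self.params["W"]
        kh, kw = self.kernel
        _, _, Ho, Wo = grad_out.shape
        dx = np.zeros_like(x)
        dW = np.zeros_like(W)
        for i in range(kh):
            for j in range(kw):
                patch = x[:, :, i:i + Ho, j:j + Wo]
                dW[:, :, i, j] = np.einsum("bchw,bohw->oc", patch, grad_out,
                                           optimize=True)
                dx[:, :, i:i + Ho, j:j + Wo] += np.einsum(
                    "bohw,oc->bchw", grad_out, W[:, :, i, j], optimize=True)
        self.grads["W"] = dW
        self.grads["b"] = grad_out.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (batch, height, width).

    A batch of one sample still normalizes over its spatial extent, so
    single-window inference is safe; running statistics are used in eval.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (grad_out * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = grad_out.sum(axis=(0, 2, 3))
        dxhat = grad_out * gamma[None, :, None, None]
        if not training:
            return dxhat * inv_std[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class MaxPool2d(Layer):
    """Max pooling with stride equal to the pool size; trailing rows/columns
    that do not fill a full pool window are cropped (floor semantics)."""

    def __init__(self, pool: tuple[int, int]) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        ph, pw = self.pool
        B, C, H, W = x.shape
        Ho, Wo = H // ph, W // pw
        if Ho == 0 or Wo == 0:
            raise ValueError(f"input {H}x{W} too small for {ph}x{pw} pooling")
        xc = x[:, :, :Ho * ph, :Wo * pw]
        r = xc.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(B, C, Ho, Wo, ph * pw)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        ph, pw = self.pool
        B, C, H, W = shape
        Ho, Wo = H // ph, W // pw
        flat = np.zeros((B, C, Ho, Wo, ph * pw), dtype=grad_out.dtype)
        np.put_along_axis(flat, idx[..., None], grad_out[..., None], axis=-1)
        dxc = flat.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(shape, dtype=grad_out.dtype)
        dx[:, :, :Ho * ph, :Wo * pw] = dxc.reshape(B, C, Ho * ph, Wo * pw)
        return dx


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.slope = negative_slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = (x >= 0,)
        return np.where(self._cache[0], x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        (pos,) = self._cache
        return np.where(pos, grad_out, self.slope * grad_out)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = (rng.standard_normal((in_features, out_features))
                            * scale).astype(dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = (x,)
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        self.grads["W"] = x.T @ grad_out
        self.grads["b"] = grad_out.sum(axis=0)
        return grad_out @ self.params["W"].T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One direction of an LSTM over (batch, time, features) input."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.hidden = hidden
        k = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wx": rng.uniform(-k, k, (in_features, 4 * hidden)).astype(dtype),
            "Wh": rng.uniform(-k, k, (hidden, 4 * hidden)).astype(dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.zeros((B, T, H), dtype=x.dtype)
        cache = []
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h = o * tanh_c
            hs[:, t] = h
            cache.append((x[:, t], h.copy(), c, i, f, g, o, c_new, tanh_c))
            c = c_new
        self._cache = (x.shape, cache)
        return hs

    def backward(self, grad_hs: np.ndarray) -> np.ndarray:
        shape, cache = self._cache
        B, T, F = shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros(shape, dtype=grad_hs.dtype)
        dh_next = np.zeros((B, H), dtype=grad_hs.dtype)
        dc_next = np.zeros((B, H), dtype=grad_hs.dtype)
        for t in range(T - 1, -1, -1):
            xt, _, c_prev, i, f, g, o, c_new, tanh_c = cache[t]
            dh = grad_hs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ], axis=1)
            dWx += xt.T @ dz
            h_prev = cache[t - 1][1] if t > 0 else np.zeros((B, H), dtype=dz.dtype)
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full sequence, width 2 x hidden."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.hidden = hidden
        self.fwd = _LSTMDirection(in_features, hidden, rng, dtype)
        self.bwd = _LSTMDirection(in_features, hidden, rng, dtype)
        for name, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in d.params.items():
                self.params[f"{name}_{k}"] = v
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(grad_out[..., :H])
        dxb = self.bwd.backward(grad_out[:, ::-1, H:])[:, ::-1]
        for name, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in d.grads.items():
                self.grads[f"{name}_{k}"] = v
        return dxf + dxb


class DualBranchNet:
    """Parallel CNN + stacked-BiLSTM branches over the same epoch grid.

    The CNN branch consumes the [channels x rows x cols] grid; the
    recurrent branch consumes the same epoch as a sequence of ``channels``
    time steps with ``rows*cols`` features. Flattened branch outputs are
    concatenated and mapped to two logits.
    """

    def __init__(self, cnn_layers: Sequence[Layer], lstm_layers: Sequence[Layer],
                 head: Linear) -> None:
        self.cnn_layers = list(cnn_layers)
        self.lstm_layers = list(lstm_layers)
        self.head = head

    @property
    def layers(self) -> list[Layer]:
        return self.cnn_layers + self.lstm_layers + [self.head]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, R, Cols = x.shape
        a = x
        for layer in self.cnn_layers:
            a = layer.forward(a, training)
        cnn_flat = a.reshape(B, -1)

        s = x.reshape(B, C, R * Cols)
        for layer in self.lstm_layers:
            s = layer.forward(s, training)
        lstm_flat = s.reshape(B, -1)

        self._shapes = (a.shape, s.shape)
        fused = np.concatenate([cnn_flat, lstm_flat], axis=1)
        return self.head.forward(fused, training)

    def backward(self, grad_logits: np.ndarray) -> None:
        cnn_shape, lstm_shape = self._shapes
        B = grad_logits.shape[0]
        d_fused = self.head.backward(grad_logits)
        n_cnn = int(np.prod(cnn_shape[1:]))
        d_cnn = d_fused[:, :n_cnn].reshape(cnn_shape)
        d_lstm = d_fused[:, n_cnn:].reshape(lstm_shape)
        for layer in reversed(self.cnn_layers):
            d_cnn = layer.backward(d_cnn)
        for layer in reversed(self.lstm_layers):
            d_lstm = layer.backward(d_lstm)

    # -- bookkeeping -------------------------------------------------------
    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.parameters())

    def checksum(self) -> str:
        """Stable digest of all parameter values (init reproducibility)."""
        h = hashlib.sha256()
        for layer, k in self.parameters():
            h.update(np.ascontiguousarray(layer.params[k], dtype=np.float64).tobytes())
        return h.hexdigest()

    def state_dict(self) -> list[np.ndarray]:
        return [layer.params[k].copy() for layer, k in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for (layer, k), v in zip(self.parameters(), state):
            layer.params[k][...] = v


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with (coupled) L2 weight decay, matching the common convention
    of adding ``weight_decay * param`` to the gradient."""

    def __init__(self, model: DualBranchNet, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, k) in enumerate(self.model.parameters()):
            g = layer.grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[k]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.model.layers:
            layer.zero_grad()


class ReduceLROnPlateau:
    """Multiply the optimizer's LR by ``factor`` after ``patience`` epochs
    without improvement of the monitored (minimized) quantity."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 10,
                 min_lr: float = 0.0) -> None:
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> None:
        if value < self.best:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
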