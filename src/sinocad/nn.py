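"""Minimal CPU neural-network engine.

Implements exactly the pieces the nodule false-positive-reduction networks
need: same-padding stride-1 convolution (im2col), 2x2/stride-2 max pooling,
LeakyReLU, dense layers, a softmax cross-entropy head, the Adam optimizer
and an early-stopping training loop.  Everything is float32 and fully
deterministic given a seed.

Array layout is channels-last: ``(batch, height, width, channels)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

_F32 = np.float32


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1, same-padding 2-D convolution via im2col.

    Weights have shape ``(k, k, c_in, c_out)``; He-style fan-in
    initialisation with a caller-provided RNG keeps runs reproducible.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = int(kernel)
        self.c_in, self.c_out = int(c_in), int(c_out)
        fan_in = self.k * self.k * self.c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(self.k, self.k, c_in, c_out))
        self.W = w.astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (n, H, W, k, k, c) windows -> rows of length k*k*c
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, H, W, c, k, k) -> (n, H, W, k, k, c)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        n, H, W = x.shape[0], x.shape[1], x.shape[2]
        return np.ascontiguousarray(win).reshape(n * H * W, k * k * self.c_in)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, H, W, _ = x.shape
        col = self._im2col(x)
        out = col @ self.W.reshape(-1, self.c_out) + self.b
        if train:
            self._cache = (x.shape, col)
        return out.reshape(n, H, W, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, H, W, _), col = self._cache
        g = grad.reshape(n * H * W, self.c_out)
        self.grads[0][...] = (col.T @ g).reshape(self.W.shape)
        self.grads[1][...] = g.sum(axis=0)
        dcol = g @ self.W.reshape(-1, self.c_out).T  # (nHW, k*k*c_in)
        k, p = self.k, self.k // 2
        dcol = dcol.reshape(n, H, W, k, k, self.c_in)
        dxp = np.zeros((n, H + 2 * p, W + 2 * p, self.c_in), dtype=_F32)
        for i in range(k):  # k*k vectorised scatter-adds
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p:p + H, p:p + W, :]


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (inputs must have even H and W)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, H, W, c = x.shape
        r = x.reshape(n, H // 2, 2, W // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, H // 2, W // 2, c, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, H, W, c), idx = self._cache
        dr = np.zeros((n, H // 2, W // 2, c, 4), dtype=_F32)
        np.put_along_axis(dr, idx[..., None], grad[..., None], axis=-1)
        dr = dr.reshape(n, H // 2, W // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dr.reshape(n, H, W, c)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        super().__init__()
        self.alpha = float(alpha)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(_F32)
        self.b = np.zeros(d_out, dtype=_F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


class Sequential:
    """A linear stack of layers ending in raw logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def output_shapes(self, input_shape: tuple[int, ...]) -> list[tuple[int, ...]]:
        """Per-layer output shapes (batch axis omitted) for a dry run."""
        x = np.zeros((1,) + tuple(input_shape), dtype=_F32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x)
            shapes.append(x.shape[1:])
        return shapes


class DualBranch:
    """Two convolutional branches whose flattened outputs feed a shared head.

    ``forward`` takes a pair ``(x_a, x_b)``; the head receives the
    concatenation of the flattened branch outputs.
    """

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a, self.branch_b, self.head = branch_a, branch_b, head

    def forward(self, x: tuple[np.ndarray, np.ndarray], train: bool = False) -> np.ndarray:
        xa, xb = x
        fa = self.branch_a.forward(xa, train=train).reshape(xa.shape[0], -1)
        fb = self.branch_b.forward(xb, train=train).reshape(xb.shape[0], -1)
        if train:
            self._split = fa.shape[1]
            self._sa, self._sb = xa.shape, xb.shape
        return self.head.forward(np.concatenate([fa, fb], axis=1), train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        ga, gb = g[:, : self._split], g[:, self._split:]
        self.branch_a.backward(ga.reshape((self._sa[0],) + self._branch_out(self.branch_a, self._sa)))
        self.branch_b.backward(gb.reshape((self._sb[0],) + self._branch_out(self.branch_b, self._sb)))

    @staticmethod
    def _branch_out(branch: Sequential, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        h, w, c = in_shape[1], in_shape[2], in_shape[3]
        for layer in branch.layers:
            if isinstance(layer, MaxPool2):
                h, w = h // 2, w // 2
            elif isinstance(layer, Conv2D):
                c = layer.c_out
        return (h, w, c)

    @property
    def params(self) -> list[np.ndarray]:
        return self.branch_a.params + self.branch_b.params + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.branch_a.grads + self.branch_b.grads + self.head.grads

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


try:                                      # fused single-pass update if numba is present
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _adam_update(p, g, m, v, b1, b2, lr_c1, inv_sqrt_c2, eps):  # pragma: no cover
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr_c1 * m[i] / (np.sqrt(v[i]) * inv_sqrt_c2 + eps)
except ImportError:                        # pure-numpy fallback
    def _adam_update(p, g, m, v, b1, b2, lr_c1, inv_sqrt_c2, eps):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * np.square(g)
        denom = np.sqrt(v)
        denom *= inv_sqrt_c2
        denom += eps
        np.divide(m, denom, out=denom)
        denom *= lr_c1
        p -= denom


class Adam:
    """Adam optimizer (defaults match the training protocol: lr 1e-4)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.beta1 ** self.t
        c2 = 1.0 - self.beta2 ** self.t
        lr_c1 = _F32(self.lr / c1)
        inv_sqrt_c2 = _F32(1.0 / np.sqrt(c2))
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            _adam_update(p.ravel(), g.ravel(), m.ravel(), v.ravel(),
                         _F32(self.beta1), _F32(self.beta2), lr_c1,
                         inv_sqrt_c2, _F32(self.eps))


@dataclass
class FitLog:
    """Per-epoch training history."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _slice_x(x, idx):
    if isinstance(x, tuple):
        return tuple(xi[idx] for xi in x)
    return x[idx]


def _n_samples(x) -> int:
    return x[0].shape[0] if isinstance(x, tuple) else x.shape[0]


def fit(model, x, y, *, epochs: int = 25, batch_size: int = 30,
        lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
        val_fraction: float = 0.1, patience: int = 5, min_delta: float = 0.0,
        seed: int = 0) -> FitLog:
    """Train ``model`` with Adam, minibatches and early stopping.

    A ``val_fraction`` slice of the training data is held out to monitor
    validation loss; training stops once it fails to improve by more than
    ``min_delta`` for ``patience`` consecutive epochs and the best weights
    are restored.  ``patience <= 0`` or ``val_fraction <= 0`` disables
    early stopping.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(x)
    use_val = val_fraction > 0 and patience > 0 and n >= 10
    if use_val:
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_val, y_val = _slice_x(x, val_idx), y[val_idx]
        x_tr, y_tr = _slice_x(x, tr_idx), y[tr_idx]
    else:
        x_tr, y_tr = x, y
        x_val = y_val = None

    opt = Adam(model.params, lr=lr, beta1=beta1, beta2=beta2)
    log = FitLog()
    best_loss, best_params, since_best = np.inf, None, 0
    n_tr = _n_samples(x_tr)
    for epoch in range(epochs):
        losses, correct = [], 0
        for idx in _batches(n_tr, batch_size, rng):
            xb, yb = _slice_x(x_tr, idx), y_tr[idx]
            probs = softmax(model.forward(xb, train=True))
            losses.append(cross_entropy(probs, yb) * len(yb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model.backward((grad / len(yb)).astype(_F32))
            opt.step(model.grads)
        log.train_loss.append(float(np.sum(losses) / n_tr))
        log.train_acc.append(correct / n_tr)
        log.stopped_epoch = epoch + 1
        if use_val:
            vl = cross_entropy(softmax(model.forward(x_val)), y_val)
            log.val_loss.append(vl)
            if vl < best_loss - max(min_delta, 1e-6):
                best_loss, since_best = vl, 0
                best_params = [p.copy() for p in model.params]
                log.best_epoch = epoch + 1
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if use_val and best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return log


def predict_proba(model, x, batch_size: int = 256) -> np.ndarray:
    """Batched softmax probabilities; identical to per-sample evaluation."""
    n = _n_samples(x)
    out = []
    for i in range(0, n, batch_size):
        out.append(softmax(model.forward(_slice_x(x, slice(i, i + batch_size)))))
    return np.concatenate(out, axis=0)
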