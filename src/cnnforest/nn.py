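"""Minimal numpy implementation of the small convolutional net.

Only what the feature extractor needs: valid-padding strided conv layers,
ReLU, flatten, dense layers, a hinge loss with L2 weight decay, and the
Adagrad / RMSProp / Adam update rules.  Forward and backward passes are
vectorised with an im2col formulation; everything is float32 and driven by
an explicit :class:`numpy.random.Generator` so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def _init_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(1.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D:
    """Valid-padding strided 2-D convolution, NCHW layout."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int], stride: int,
                 rng: np.random.Generator):
        kh, kw = kernel_size
        fan_in = in_channels * kh * kw
        self.W = _init_uniform((out_channels, in_channels, kh, kw), fan_in, rng)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.stride = stride
        self.kernel_size = (kh, kw)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    # -- im2col -----------------------------------------------------------
    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel_size
        s = self.stride
        return (h - kh) // s + 1, (w - kw) // s + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        kh, kw = self.kernel_size
        s = self.stride
        oh, ow = self._out_hw(h, w)
        cols = np.empty((n, c, kh, kw, oh, ow), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = x[:, :, i : i + s * oh : s, j : j + s * ow : s]
        return cols.reshape(n, c * kh * kw, oh * ow)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        cols = self._im2col(x)
        if train:
            self._cols, self._x_shape = cols, x.shape
        wmat = self.W.reshape(self.W.shape[0], -1)  # (F, C*kh*kw)
        out = np.einsum("fk,nkp->nfp", wmat, cols) + self.b[None, :, None]
        return out.reshape(n, self.W.shape[0], oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, f, oh, ow = grad.shape
        g = grad.reshape(n, f, oh * ow)
        cols = self._cols
        self.dW = np.einsum("nfp,nkp->fk", g, cols).reshape(self.W.shape)
        self.db = g.sum(axis=(0, 2))
        wmat = self.W.reshape(f, -1)
        dcols = np.einsum("fk,nfp->nkp", wmat, g)  # (n, C*kh*kw, P)
        # col2im: scatter-add patches back
        _, c, h, w = self._x_shape
        kh, kw = self.kernel_size
        s = self.stride
        dcols = dcols.reshape(n, c, kh, kw, oh, ow)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        self._cols = None
        return dx

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]

    regularized = (True, False)  # W yes, b no


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []

    regularized = ()


class Flatten:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def params(self):
        return []

    regularized = ()


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _init_uniform((in_features, out_features), in_features, rng)
        self.b = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        return dx

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]

    regularized = (True, False)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def weight_arrays(self) -> list[np.ndarray]:
        """All parameter arrays, in a stable order (for persistence)."""
        out = []
        for layer in self.layers:
            out.extend(p for p, _ in layer.params())
        return out

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        current = self.weight_arrays()
        if len(current) != len(arrays):
            raise ValueError("weight count mismatch")
        for dst, src in zip(current, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"weight shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def copy_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weight_arrays()]

    def l2_penalty(self, coeff: float) -> float:
        total = 0.0
        for layer in self.layers:
            for (p, _), reg in zip(layer.params(), layer.regularized):
                if reg:
                    total += float(np.sum(p.astype(np.float64) ** 2))
        return coeff * total

    def apply_l2_gradients(self, coeff: float) -> None:
        for layer in self.layers:
            for (p, gname), reg in zip(layer.params(), layer.regularized):
                if reg:
                    grad = getattr(layer, gname)
                    grad += 2.0 * coeff * p


def hinge_loss(scores: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean hinge loss max(0, 1 - y*s) over targets y in {-1, +1}.

    Returns (loss, dloss/dscores).
    """
    scores = scores.reshape(-1)
    margins = 1.0 - targets * scores
    active = margins > 0
    loss = float(np.mean(np.maximum(margins, 0.0)))
    grad = np.where(active, -targets, 0.0) / scores.shape[0]
    return loss, grad.astype(np.float32).reshape(-1, 1)


class _Optimizer:
    def __init__(self, learning_rate: float):
        self.lr = learning_rate
        self._state: dict[int, dict] = {}

    def step(self, model: Sequential) -> None:
        for layer in model.layers:
            for p, gname in layer.params():
                g = getattr(layer, gname)
                state = self._state.setdefault(id(p), self._init_state(p))
                self._update(p, g.astype(np.float32), state)

    def _init_state(self, p: np.ndarray) -> dict:
        raise NotImplementedError

    def _update(self, p: np.ndarray, g: np.ndarray, state: dict) -> None:
        raise NotImplementedError


class Adagrad(_Optimizer):
    default_lr = 0.01

    def _init_state(self, p):
        return {"acc": np.zeros_like(p)}

    def _update(self, p, g, state):
        state["acc"] += g * g
        p -= self.lr * g / (np.sqrt(state["acc"]) + EPS)


class RMSProp(_Optimizer):
    default_lr = 0.001
    rho = 0.9

    def _init_state(self, p):
        return {"acc": np.zeros_like(p)}

    def _update(self, p, g, state):
        state["acc"] = self.rho * state["acc"] + (1.0 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(state["acc"]) + EPS)


class Adam(_Optimizer):
    default_lr = 0.001
    beta1 = 0.9
    beta2 = 0.999

    def _init_state(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0}

    def _update(self, p, g, state):
        state["t"] += 1
        state["m"] = self.beta1 * state["m"] + (1 - self.beta1) * g
        state["v"] = self.beta2 * state["v"] + (1 - self.beta2) * g * g
        mhat = state["m"] / (1 - self.beta1 ** state["t"])
        vhat = state["v"] / (1 - self.beta2 ** state["t"])
        p -= self.lr * mhat / (np.sqrt(vhat) + EPS)


OPTIMIZERS = {"adagrad": Adagrad, "rmsprop": RMSProp, "adam": Adam}


def make_optimizer(name: str, learning_rate: float | None = None) -> _Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    cls = OPTIMIZERS[key]
    return cls(cls.default_lr if learning_rate is None else learning_rate)
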