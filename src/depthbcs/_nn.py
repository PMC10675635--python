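"""Minimal NumPy CNN engine: layers, losses, Adam, and a Sequential container.

Small by design — it implements exactly what the fusion classifiers need:
3x3 "same" convolutions, 2x2 max pooling, dense layers, ReLU, softmax with
per-class-weighted cross-entropy, and Adam. All computation is float32 and
deterministic given the seed of the generator used for initialization and
shuffling.

Array layout is channels-last: (N, H, W, C).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "MaxPool2", "Flatten", "Dense", "ReLU",
    "Sequential", "Adam", "softmax", "weighted_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           class_weights: np.ndarray | None = None,
                           ) -> tuple[float, np.ndarray]:
    """Mean per-sample-weighted CE loss and its gradient w.r.t. logits.

    ``loss = (1/N) sum_i w_{y_i} * (-log p_i[y_i])`` — the keras-style
    class_weight convention.
    """
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(k, dtype=np.float64) if class_weights is None else np.asarray(class_weights)
    wy = w[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(-(wy * logp).mean())
    grad = p.astype(np.float64)
    grad[np.arange(n), y] -= 1.0
    grad *= wy[:, None] / n
    return loss, grad.astype(np.float32)


class Layer:
    trainable: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params_grads())

    def flops(self, input_shape: tuple) -> tuple[int, tuple]:
        """(multiply-adds for one sample, output shape)."""
        return 0, input_shape


class Conv2D(Layer):
    """3x3-style 'same' convolution with bias, He-normal init."""

    trainable = True

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        scale = np.sqrt(2.0 / (kernel * kernel * in_ch))
        self.W = rng.normal(0, scale, (kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xpad = xpad
        out = np.broadcast_to(self.b, (n, h, w, self.b.size)).copy()
        for di in range(k):
            for dj in range(k):
                out += xpad[:, di:di + h, dj:dj + w, :] @ self.W[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        xpad = self._xpad
        assert xpad is not None
        n, h, w, _ = dout.shape
        self.db[:] = dout.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(xpad)
        for di in range(k):
            for dj in range(k):
                patch = xpad[:, di:di + h, dj:dj + w, :]
                self.dW[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxpad[:, di:di + h, dj:dj + w, :] += dout @ self.W[di, dj].T
        p = k // 2
        return dxpad[:, p:p + h, p:p + w, :] if p else dxpad

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def flops(self, input_shape):
        h, w, cin = input_shape
        cout = self.b.size
        macs = h * w * self.k * self.k * cin * cout
        return macs, (h, w, cout)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xt = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._arg = xt.argmax(axis=-1)
        self._inshape = x.shape
        return xt.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        dx4 = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dx4, self._arg[..., None], dout[..., None], axis=-1)
        dx4 = dx4.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._inshape, dtype=dout.dtype)
        dx[:, :h2 * 2, :w2 * 2, :] = dx4.reshape(n, h2 * 2, w2 * 2, c)
        return dx

    def flops(self, input_shape):
        h, w, c = input_shape
        return 0, (h // 2, w // 2, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._inshape)

    def flops(self, input_shape):
        return 0, (int(np.prod(input_shape)),)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def flops(self, input_shape):
        return self.W.shape[0] * self.W.shape[1], (self.W.shape[1],)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sequential:
    """An ordered stack of layers with shared parameter/grad bookkeeping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params_grads())

    def flops(self, input_shape: tuple) -> int:
        """Total FLOPs (2 x multiply-adds) for one sample."""
        macs = 0
        shape = input_shape
        for layer in self.layers:
            m, shape = layer.flops(shape)
            macs += m
        return 2 * macs

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params_grads(), weights):
            p[...] = w


def _iter_layers(net):
    if hasattr(net, "layers"):
        yield from net.layers
    else:   # multi-trunk network: trunks then head
        for trunk in net.trunks:
            yield from trunk.layers
        yield from net.head.layers


def reinitialize(net, rng: np.random.Generator) -> None:
    """Redraw all trainable weights (He-normal) in place; biases to zero."""
    for layer in _iter_layers(net):
        if isinstance(layer, Conv2D):
            scale = np.sqrt(2.0 / (layer.k * layer.k * layer.W.shape[2]))
        elif isinstance(layer, Dense):
            scale = np.sqrt(2.0 / layer.W.shape[0])
        else:
            continue
        layer.W[...] = rng.normal(0, scale, layer.W.shape).astype(np.float32)
        layer.b[...] = 0


class Adam:
    def __init__(self, params_grads, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.pg = params_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
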