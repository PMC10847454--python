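"""Layer objects with explicit forward/backward passes.

Each layer caches whatever it needs from the forward pass and consumes it in
``backward``. Models compose layers by hand (see ``segmenter``/``classifier``),
which keeps the graph explicit — there is no autograd tape.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, 'same' padding, odd kernel, He-normal init."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 skip_input_grad: bool = False):
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, scale, (cout, cin, kernel, kernel, kernel)))
        self.b = Param(np.zeros(cout))
        self.stride = stride
        self.skip_input_grad = skip_input_grad  # first layer: dx is never used
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        y, self._cols = F.conv3d_forward(x, self.w.value, self.b.value,
                                         self.stride, return_cols=True)
        return y

    def backward(self, dy):
        dx, dw, db = F.conv3d_backward(self._x, self.w.value, dy, self.stride,
                                       compute_dx=not self.skip_input_grad,
                                       cols=self._cols)
        self._cols = None
        self.w.grad += dw
        self.b.grad += db
        return dx


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)))
        self.b = Param(np.zeros(nout))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout; ``active`` is controlled by the owning model.

    At inference the layer is a no-op unless Monte Carlo sampling re-activates
    it, in which case masks are drawn from ``rng`` (reseedable for
    reproducible stochastic passes).
    """

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng
        self.active = False
        self._mask: np.ndarray | None = None

    def forward(self, x):
        if not self.active or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * self._mask / (1.0 - self.p)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask / (1.0 - self.p)


class AvgPool2(Layer):
    def forward(self, x):
        self._shape = x.shape
        return F.avgpool2_forward(x)

    def backward(self, dy):
        return F.avgpool2_backward(dy)


class Upsample2(Layer):
    def forward(self, x):
        return F.upsample2_forward(x)

    def backward(self, dy):
        return F.upsample2_backward(dy)


class GlobalAvgPool(Layer):
    """(N,C,D,H,W) -> (N,C)."""

    def forward(self, x):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        d, h, w = self._spatial
        g = dy[:, :, None, None, None] / float(d * h * w)
        return np.broadcast_to(g, dy.shape + self._spatial).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
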