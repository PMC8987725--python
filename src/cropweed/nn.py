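"""A compact feed-forward CNN engine on flat numpy parameter vectors.

All trainable weights of a network live in one flat float64 vector, so
gradient-step arithmetic (SGD, the meta-learning inner/outer updates,
per-group learning-rate scaling) is plain vector algebra.  Layers implement
forward and backward passes explicitly; convolution uses sliding-window
views + einsum.  Data layout is NHWC.

This is intentionally a small engine for small models: four conv/pool
stages plus a linear readout on patches up to a few hundred pixels a side.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Shift", "Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Flatten",
           "Dense", "Net", "build_meta_cnn", "build_toy_backbone", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """One stage of a network.  Parametric layers override param_shapes."""

    def param_shapes(self, in_shape):
        return []

    def out_shape(self, in_shape):
        raise NotImplementedError

    def init_params(self, in_shape, rng):
        return []

    def forward(self, x, params):
        """Return (y, cache)."""
        raise NotImplementedError

    def backward(self, dy, cache, params):
        """Return (dx, [dparam, ...])."""
        raise NotImplementedError


class Shift(Layer):
    """Fixed additive input offset (e.g. -0.5 to center reflectance)."""

    def __init__(self, offset: float):
        self.offset = offset

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, params):
        return x + self.offset, None

    def backward(self, dy, cache, params):
        return dy, []


class Conv2D(Layer):
    """3x3 (configurable, odd) same-padding stride-1 convolution + bias."""

    def __init__(self, out_channels: int, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.out_channels = out_channels
        self.kernel = kernel

    def param_shapes(self, in_shape):
        h, w, c = in_shape
        return [(self.kernel, self.kernel, c, self.out_channels), (self.out_channels,)]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h, w, self.out_channels)

    def init_params(self, in_shape, rng):
        (kh, kw, c, oc), _ = self.param_shapes(in_shape)
        fan_in = kh * kw * c
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c, oc))
        return [w, np.zeros(oc)]

    def _cols(self, x):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (B, H, W, C, kh, kw)
        return np.lib.stride_tricks.sliding_window_view(xp, (self.kernel, self.kernel), axis=(1, 2))

    def forward(self, x, params):
        w, b = params
        cols = self._cols(x)
        y = np.einsum("bhwcij,ijco->bhwo", cols, w, optimize=True) + b
        return y, (x, cols)

    def backward(self, dy, cache, params):
        w, _ = params
        x, cols = cache
        dw = np.einsum("bhwcij,bhwo->ijco", cols, dy, optimize=True)
        db = dy.sum(axis=(0, 1, 2))
        p = self.kernel // 2
        b_, h, w_, _ = x.shape
        dxp = np.zeros((b_, h + 2 * p, w_ + 2 * p, x.shape[3]))
        for i in range(self.kernel):
            for j in range(self.kernel):
                dxp[:, i : i + h, j : j + w_, :] += np.einsum(
                    "bhwo,co->bhwc", dy, w[i, j], optimize=True
                )
        dx = dxp[:, p : p + h, p : p + w_, :]
        return dx, [dw, db]


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, params):
        y = np.maximum(x, 0.0)
        return y, (x > 0)

    def backward(self, dy, cache, params):
        return dy * cache, []


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h // 2, w // 2, c)

    def forward(self, x, params):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        xr = xc.reshape(b, h2, 2, w2, 2, c)
        y = xr.max(axis=(2, 4))
        # ties share gradient equally (counts divisor in backward)
        mask = xr == y[:, :, None, :, None, :]
        return y, (mask, x.shape)

    def backward(self, dy, cache, params):
        mask, in_shape = cache
        b, h, w, c = in_shape
        h2, w2 = h // 2, w // 2
        counts = mask.sum(axis=(2, 4), keepdims=True)
        grad = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(in_shape)
        dx[:, : h2 * 2, : w2 * 2, :] = grad.reshape(b, h2 * 2, w2 * 2, c)
        return dx, []


class GlobalAvgPool(Layer):
    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (c,)

    def forward(self, x, params):
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, dy, cache, params):
        b, h, w, c = cache
        return np.broadcast_to(dy[:, None, None, :], (b, h, w, c)) / (h * w), []


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, params):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache, params):
        return dy.reshape(cache), []


class Dense(Layer):
    def __init__(self, out_features: int):
        self.out_features = out_features

    def param_shapes(self, in_shape):
        (f,) = in_shape
        return [(f, self.out_features), (self.out_features,)]

    def out_shape(self, in_shape):
        return (self.out_features,)

    def init_params(self, in_shape, rng):
        (f,) = in_shape
        w = rng.normal(0.0, np.sqrt(2.0 / f), size=(f, self.out_features))
        return [w, np.zeros(self.out_features)]

    def forward(self, x, params):
        w, b = params
        return x @ w + b, x

    def backward(self, dy, cache, params):
        w, _ = params
        return dy @ w.T, [cache.T @ dy, dy.sum(axis=0)]


class Net:
    """A sequential network over a flat parameter vector.

    The flat layout concatenates each parametric layer's arrays in order;
    ``n_params`` gives the total length and ``init_params`` a seeded
    initialization.  ``loss_and_grad`` evaluates softmax cross-entropy
    against integer labels and returns the flat gradient.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int]):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self._slices: list[list[tuple[slice, tuple]]] = []
        offset = 0
        shape = self.input_shape
        for layer in layers:
            entries = []
            for pshape in layer.param_shapes(shape):
                size = int(np.prod(pshape))
                entries.append((slice(offset, offset + size), pshape))
                offset += size
            self._slices.append(entries)
            shape = layer.out_shape(shape)
        self.output_shape = shape
        self.n_params = offset

    def init_params(self, rng: np.random.Generator | int | None = 0) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        theta = np.empty(self.n_params)
        shape = self.input_shape
        for layer, entries in zip(self.layers, self._slices):
            for arr, (sl, pshape) in zip(layer.init_params(shape, rng), entries):
                theta[sl] = np.asarray(arr).ravel()
            shape = layer.out_shape(shape)
        return theta

    def _layer_params(self, theta: np.ndarray, k: int):
        return [theta[sl].reshape(pshape) for sl, pshape in self._slices[k]]

    def forward(self, theta: np.ndarray, x: np.ndarray, return_caches: bool = False):
        x = np.asarray(x, dtype=np.float64)
        caches = []
        for k, layer in enumerate(self.layers):
            x, cache = layer.forward(x, self._layer_params(theta, k))
            caches.append(cache)
        return (x, caches) if return_caches else x

    def predict(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(theta, x), axis=-1)

    def predict_proba(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(theta, x))

    def accuracy(self, theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(theta, x) == np.asarray(y)))

    def loss(self, theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward(theta, x)
        p = softmax(logits)
        return float(-np.mean(np.log(p[np.arange(len(y)), np.asarray(y)] + 1e-300)))

    def loss_and_grad(self, theta: np.ndarray, x: np.ndarray, y: np.ndarray):
        """Mean softmax cross-entropy over the batch and its flat gradient."""
        y = np.asarray(y)
        logits, caches = self.forward(theta, x, return_caches=True)
        p = softmax(logits)
        n = len(y)
        loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = np.zeros_like(theta)
        dy = dlogits
        for k in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[k]
            dy, dparams = layer.backward(dy, caches[k], self._layer_params(theta, k))
            for arr, (sl, _) in zip(dparams, self._slices[k]):
                grad[sl] = np.asarray(arr).ravel()
        return loss, grad


def build_meta_cnn(
    in_channels: int = 3,
    side: int = 32,
    n_classes: int = 6,
    channels: tuple[int, int, int, int] = (16, 32, 64, 64),
) -> Net:
    """The 9-layer classification CNN: 4 conv, 4 max-pool, 1 fully connected
    softmax readout (3x3 kernels, ReLU after each conv).

    Inputs are reflectance in [0, 1]; a fixed -0.5 shift centers them so
    early gradients are not dominated by the common brightness component.
    """
    layers: list[Layer] = [Shift(-0.5)]
    for c in channels:
        layers += [Conv2D(c), ReLU(), MaxPool2()]
    layers += [Flatten(), Dense(n_classes)]
    return Net(layers, (side, side, in_channels))


def build_toy_backbone(
    in_channels: int = 3,
    side: int = 32,
    feature_dim: int = 32,
    hidden: int = 16,
) -> Net:
    """A small fixed conv feature extractor: conv-pool-conv-pool-GAP.

    The global average pool makes the features sensitive to per-channel
    reflectance levels, which is the dominant class signal in the synthetic
    benchmark.  Output length is ``feature_dim``.
    """
    layers = [Conv2D(hidden), ReLU(), MaxPool2(), Conv2D(feature_dim), ReLU(), MaxPool2(),
              GlobalAvgPool()]
    return Net(layers, (side, side, in_channels))
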