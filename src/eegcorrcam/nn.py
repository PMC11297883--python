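"""A compact NumPy CNN engine with exact reverse-mode gradients.

Implements the handful of layers the correlation-image classifier needs —
same-padded 2-D convolution, 2x2 max pooling with floor division, global
max pooling, dropout, dense, batch normalisation — plus the Adam optimiser
and class-weighted sparse categorical cross-entropy.  All tensors are NHWC
float32.  Convolutions are evaluated as im2col + BLAS matrix products, and
every layer implements an analytic backward pass, which both trains the
network and supplies the feature-map gradients Grad-CAM consumes.

The engine is deliberately small: stride-1 odd-kernel 'same' convolutions
and 2x2 stride-2 pooling only, which is exactly the family of shapes the
classifier architecture uses.
"""

from __future__ import annotations

import numpy as np

_F = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract k x k same-padded patches: (N,H,W,C) -> (N,H,W,k*k*C)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (N, H, W, C, k, k) -> patches ordered (k, k, C) to match the kernel
    v = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return v.reshape(n, h, w, k * k * x.shape[3])


class Layer:
    """Base class; layers cache what their backward pass needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def initialize(self, in_shape: tuple, rng: np.random.Generator) -> tuple:
        """Allocate parameters for ``in_shape`` (no batch axis); return out shape."""
        return self.output_shape(in_shape)

    def output_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(shape: tuple, fan_in: int, fan_out: int,
                    rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F)


class Conv2D(Layer):
    """Same-padded stride-1 convolution with optional ReLU."""

    def __init__(self, filters: int, kernel: int = 3, activation: str | None = "relu"):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported with 'same' padding")
        self.filters = filters
        self.kernel = kernel
        self.activation = activation

    def output_shape(self, in_shape):
        h, w, _ = in_shape
        return (h, w, self.filters)

    def initialize(self, in_shape, rng):
        h, w, c = in_shape
        k = self.kernel
        self.params["W"] = _glorot_uniform((k, k, c, self.filters),
                                           k * k * c, k * k * self.filters, rng)
        self.params["b"] = np.zeros(self.filters, dtype=_F)
        return (h, w, self.filters)

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        k = self.kernel
        cols = _im2col(x, k).reshape(n * h * w, k * k * c)
        z = cols @ self.params["W"].reshape(k * k * c, self.filters)
        z += self.params["b"]
        z = z.reshape(n, h, w, self.filters)
        self._cols, self._in_channels = cols, c
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0)
        self.output = z
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0)
        n, h, w, f = dout.shape
        k, c = self.kernel, self._in_channels
        dflat = dout.reshape(n * h * w, f)
        self.grads["W"] = (self._cols.T @ dflat).reshape(k, k, c, f)
        self.grads["b"] = dflat.sum(axis=0)
        # input gradient = convolution of dout with the 180deg-rotated,
        # channel-swapped kernel (valid for stride 1, 'same' padding)
        w_rot = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)
        cols_d = _im2col(dout, k).reshape(n * h * w, k * k * f)
        dx = cols_d @ w_rot.reshape(k * k * f, c)
        return dx.reshape(n, h, w, c)


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling; odd trailing rows/columns are dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        if pool != 2:
            raise ValueError("only 2x2 pooling supported")
        self.pool = pool

    def output_shape(self, in_shape):
        h, w, c = in_shape
        return (h // 2, w // 2, c)

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        r = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = r.reshape(n, h2, w2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]
        self.output = out
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        g = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(g, self._argmax[..., None], dout[..., None], axis=-1)
        g = g.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        g = g.reshape(n, 2 * h2, 2 * w2, c)
        if (h, w) != (2 * h2, 2 * w2):
            full = np.zeros((n, h, w, c), dtype=dout.dtype)
            full[:, : 2 * h2, : 2 * w2, :] = g
            return full
        return g


class GlobalMaxPool2D(Layer):
    """Spatial global max: (N,H,W,C) -> (N,C)."""

    def output_shape(self, in_shape):
        return (in_shape[2],)

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        self._in_shape = x.shape
        flat = x.reshape(n, h * w, c)
        self._argmax = flat.argmax(axis=1)
        out = np.take_along_axis(flat, self._argmax[:, None, :], axis=1)[:, 0, :]
        self.output = out
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        g = np.zeros((n, h * w, c), dtype=dout.dtype)
        np.put_along_axis(g, self._argmax[:, None, :], dout[:, None, :], axis=1)
        return g.reshape(n, h, w, c)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def output_shape(self, in_shape):
        return in_shape

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            self.output = x
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        out = x * self._mask
        self.output = out
        return out

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Fully connected layer; activation in {None, 'relu', 'softmax'}.

    For 'softmax' the forward pass returns probabilities, but ``backward``
    expects the gradient *with respect to the logits* — the softmax
    Jacobian is fused into the cross-entropy gradient by the caller.  This
    also lets Grad-CAM seed the backward pass with a one-hot vector to
    obtain the gradient of a single class logit.
    """

    def __init__(self, units: int, activation: str | None = None):
        super().__init__()
        self.units = units
        self.activation = activation

    def output_shape(self, in_shape):
        return (self.units,)

    def initialize(self, in_shape, rng):
        (d,) = in_shape
        self.params["W"] = _glorot_uniform((d, self.units), d, self.units, rng)
        self.params["b"] = np.zeros(self.units, dtype=_F)
        return (self.units,)

    def forward(self, x, training, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0)
        elif self.activation == "softmax":
            z = softmax(z)
        self.output = z
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0)
        # softmax: dout is already d(loss)/d(logits) (fused with the loss)
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalisation over the batch axis of a (N, D) tensor."""

    def __init__(self, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def output_shape(self, in_shape):
        return in_shape

    def initialize(self, in_shape, rng):
        (d,) = in_shape
        self.params["gamma"] = np.ones(d, dtype=_F)
        self.params["beta"] = np.zeros(d, dtype=_F)
        self.running_mean = np.zeros(d, dtype=_F)
        self.running_var = np.ones(d, dtype=_F)
        return in_shape

    def forward(self, x, training, rng=None):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(_F)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        out = self.params["gamma"] * self._xhat + self.params["beta"]
        self._training = training
        self.output = out
        return out

    def backward(self, dout):
        gamma = self.params["gamma"]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        if not self._training:
            return dout * gamma / self._std
        n = dout.shape[0]
        dxhat = dout * gamma
        return (dxhat - dxhat.mean(axis=0)
                - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """An ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.initialize(shape, rng)
        self.output_shape = shape

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=_F)
        if out.ndim == 3:
            out = out[..., None]
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x)
        parts = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(parts, axis=0)

    # -- gradients ---------------------------------------------------------
    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Backpropagate ``dout`` (gradient w.r.t. the final logits).

        Returns, per layer, the gradient with respect to that layer's
        *output*; entry ``i`` pairs with ``self.layers[i].output``.
        """
        grads_wrt_output: list[np.ndarray | None] = [None] * len(self.layers)
        g = dout
        for i in reversed(range(len(self.layers))):
            grads_wrt_output[i] = g
            g = self.layers[i].backward(g)
        return grads_wrt_output

    def shape_trace(self, input_shape: tuple | None = None) -> list[tuple]:
        """Per-layer output shapes (no batch axis) for an input shape."""
        shape = tuple(input_shape) if input_shape is not None else self.input_shape
        trace = []
        for layer in self.layers:
            shape = layer.output_shape(shape)
            trace.append(shape)
        return trace

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> list[dict[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                d["_running_mean"] = layer.running_mean.copy()
                d["_running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, d in zip(self.layers, weights):
            for k, v in d.items():
                if k == "_running_mean":
                    layer.running_mean = v.copy()
                elif k == "_running_var":
                    layer.running_var = v.copy()
                else:
                    layer.params[k] = v.copy()

    def last_conv_index(self) -> int:
        for i in reversed(range(len(self.layers))):
            if isinstance(self.layers[i], Conv2D):
                return i
        raise ValueError("network has no convolutional layer")


class Adam:
    """Adam optimiser over a network's parameters."""

    def __init__(self, network: Network, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in network.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in network.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for layer, m, v in zip(self.network.layers, self._m, self._v):
            for k, g in layer.grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                layer.params[k] -= (lr_t * m[k] / (np.sqrt(v[k]) + self.eps)).astype(_F)


def save_weights(network: Network, path) -> None:
    """Serialise network weights (and batch-norm running stats) to .npz."""
    arrays = {}
    for i, d in enumerate(network.get_weights()):
        for k, v in d.items():
            arrays[f"layer{i}/{k}"] = v
    np.savez(path, **arrays)


def load_weights(network: Network, path) -> Network:
    """Load weights saved by :func:`save_weights` into a built network."""
    with np.load(path) as data:
        weights: list[dict[str, np.ndarray]] = [{} for _ in network.layers]
        for key in data.files:
            layer_part, name = key.split("/", 1)
            weights[int(layer_part[5:])][name] = data[key]
    network.set_weights(weights)
    return network


def weighted_sparse_crossentropy(probs: np.ndarray, y: np.ndarray,
                                 sample_weight: np.ndarray | None = None
                                 ) -> tuple[float, np.ndarray]:
    """Class-weighted sparse categorical cross-entropy.

    Returns ``(loss, dlogits)`` where the gradient is taken with respect to
    the pre-softmax logits (softmax Jacobian fused in).  Loss is the mean of
    per-sample weighted losses.
    """
    n, k = probs.shape
    y = np.asarray(y, dtype=int)
    if sample_weight is None:
        sample_weight = np.ones(n)
    p_y = np.clip(probs[np.arange(n), y], 1e-12, None)
    loss = float(np.mean(sample_weight * -np.log(p_y)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    dlogits = (sample_weight[:, None] * (probs - onehot) / n).astype(probs.dtype)
    return loss, dlogits
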