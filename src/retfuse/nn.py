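"""A compact, fully seeded NumPy neural-network stack.

Implements exactly the layer vocabulary the pipeline's networks need —
same-padded stride-1 convolutions, batch normalization, ReLU, sigmoid,
2x2 max pooling, dropout, dense layers — with softmax cross-entropy and
SGD-with-momentum training. Everything is float32 and driven by a
single ``numpy.random.Generator``, so a fixed seed reproduces training
bit-for-bit on one machine. Data layout is NHWC.
"""

from __future__ import annotations

import numpy as np

F = np.float32


class Layer:
    """Base layer: stateless unless it declares params/grads dicts."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def init(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        return in_shape

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, 'same' zero padding."""

    def __init__(self, out_channels: int, kernel: int) -> None:
        super().__init__()
        self.oc = out_channels
        self.k = kernel

    def init(self, rng, in_shape):
        h, w, c = in_shape
        self.ic = c
        fan_in = self.k * self.k * c
        scale = np.sqrt(2.0 / fan_in)
        self.params["W"] = (rng.standard_normal((self.k * self.k * c, self.oc)) * scale).astype(F)
        self.params["b"] = np.zeros(self.oc, dtype=F)
        return (h, w, self.oc)

    @property
    def n_parameters(self) -> int:
        return self.params["W"].size + self.params["b"].size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> (n*h*w, k*k*c) matching W layout (i, j, c)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, self.k * self.k * c)
        return np.ascontiguousarray(cols, dtype=F)

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self.cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.oc)

    def backward(self, dout):
        n, h, w, _ = self.x_shape
        dout_mat = dout.reshape(n * h * w, self.oc).astype(F)
        self.grads["W"] = self.cols.T @ dout_mat
        self.grads["b"] = dout_mat.sum(axis=0)
        dcols = (dout_mat @ self.params["W"].T).reshape(n, h, w, self.k, self.k, self.ic)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.ic), dtype=F)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self.cols = None
        return dxp[:, p:p + h, p:p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def init(self, rng, in_shape):
        c = in_shape[-1]
        self.params["gamma"] = np.ones(c, dtype=F)
        self.params["beta"] = np.zeros(c, dtype=F)
        self.running_mean = np.zeros(c, dtype=F)
        self.running_var = np.ones(c, dtype=F)
        self.calibrating = False
        self._cal_means: list[np.ndarray] = []
        self._cal_vars: list[np.ndarray] = []
        return in_shape

    def start_calibration(self) -> None:
        self.calibrating = True
        self._cal_means, self._cal_vars = [], []

    def finish_calibration(self) -> None:
        # law of total variance over equally weighted batches
        means = np.stack(self._cal_means)
        self.running_mean = means.mean(axis=0).astype(F)
        self.running_var = (np.stack(self._cal_vars).mean(axis=0)
                            + means.var(axis=0)).astype(F)
        self.calibrating = False
        self._cal_means, self._cal_vars = [], []

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F)
        elif self.calibrating:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self._cal_means.append(np.asarray(mean))
            self._cal_vars.append(np.asarray(var))
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean) * self.inv_std
        self.m = np.prod([x.shape[a] for a in axes])
        return (self.params["gamma"] * self.xhat + self.params["beta"]).astype(F)

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * self.xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dout * g
        dx = (self.inv_std / self.m) * (
            self.m * dxhat
            - dxhat.sum(axis=axes)
            - self.xhat * (dxhat * self.xhat).sum(axis=axes)
        )
        self.xhat = None
        return dx.astype(F)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class Sigmoid(Layer):
    def forward(self, x, train, rng):
        self.out = 1.0 / (1.0 + np.exp(-x))
        return self.out.astype(F)

    def backward(self, dout):
        return (dout * self.out * (1.0 - self.out)).astype(F)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def init(self, rng, in_shape):
        h, w, c = in_shape
        return (h // 2, w // 2, c)

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self.in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        xr = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self.argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self.in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, c, 4), dtype=F)
        np.put_along_axis(dxr, self.argmax[..., None], dout[..., None].astype(F), axis=-1)
        dx = np.zeros((n, h, w, c), dtype=F)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dxr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx


class Dropout(Layer):
    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) >= self.p).astype(F) / F(1.0 - self.p)
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask


class Flatten(Layer):
    def init(self, rng, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train, rng):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.in_shape)


class Dense(Layer):
    def __init__(self, out_features: int) -> None:
        super().__init__()
        self.of = out_features

    def init(self, rng, in_shape):
        (din,) = in_shape
        scale = np.sqrt(2.0 / din)
        self.params["W"] = (rng.standard_normal((din, self.of)) * scale).astype(F)
        self.params["b"] = np.zeros(self.of, dtype=F)
        return (self.of,)

    def forward(self, x, train, rng):
        self.x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        dout = dout.astype(F)
        self.grads["W"] = self.x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self.x = None
        return dx


def softmax(x: np.ndarray) -> np.ndarray:
    """Shift-stable softmax along the last axis."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class (CL >= 0)."""
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels], 1e-12, 1.0)
    return float(-np.log(p).mean())


class Sequential:
    """An ordered layer stack with explicit init/forward/backward."""

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.init(self.rng, shape)
        self.output_shape = shape

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=F)
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def recalibrate_batchnorm(self, x: np.ndarray, batch_size: int = 32) -> None:
        """Reset BatchNorm running statistics from clean full-data passes.

        Exponential running averages collected during training reflect
        dropout-perturbed, small-batch activations; inference statistics
        are re-estimated here with dropout off.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        if not bns:
            return
        for layer in bns:
            layer.start_calibration()
        for start in range(0, len(x), batch_size):
            self.forward(x[start:start + batch_size], train=False)
        for layer in bns:
            layer.finish_calibration()

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"{i}.{name}"] = value
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].astype(F)
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].astype(F)
                layer.running_var = state[f"{i}.running_var"].astype(F)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Sequential, lr: float = 0.01, momentum: float = 0.9) -> None:
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.velocity = {
            (id(layer), name): np.zeros_like(layer.params[name])
            for layer, name in model.parameters()
        }

    def step(self) -> None:
        for layer, name in self.model.parameters():
            key = (id(layer), name)
            v = self.velocity[key]
            v *= F(self.momentum)
            v -= F(self.lr) * layer.grads[name]
            layer.params[name] += v
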