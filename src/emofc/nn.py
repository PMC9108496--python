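"""A compact numpy CNN built on depthwise-separable convolutions.

The classifier mirrors the Xception design idea: residual modules whose main
path stacks depthwise-separable convolutions (per-channel 3x3 spatial
filtering followed by a 1x1 pointwise mix), with strided 1x1 shortcuts, a
global-average-pooling head and a softmax output. Two scales are provided:

* ``full`` — 14 residual modules containing 3 standard and 33 separable
  convolution layers, the reference architecture's layer budget (built and
  forward-capable; far larger than the toy inputs here require);
* ``mini`` — a stem convolution plus 2 separable residual modules, the
  desk-scale model trained throughout the test-suite and pipeline runs.

Everything is implemented directly in numpy (im2col convolutions, manual
backpropagation, Adam), so training is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["build_model", "SoftmaxClassifier", "resize_nearest"]


def resize_nearest(images: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize of (N, C, H, W) images; adds no new intensities."""
    n, c, h, w = images.shape
    th, tw = size
    rows = np.floor((np.arange(th) + 0.5) * h / th).astype(int)
    cols = np.floor((np.arange(tw) + 0.5) * w / tw).astype(int)
    return images[:, :, rows][:, :, :, cols]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[list[np.ndarray]]:
        """Pairs [param, grad] updated in place by the optimizer."""
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Layer):
    """Standard convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.standard_normal((cout, cin * k * k)) * scale
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.pad = k // 2

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        ho = (h + 2 * self.pad - k) // s + 1
        wo = (w + 2 * self.pad - k) // s + 1
        xp = _pad(x, self.pad)
        cols = np.empty((n, c, k * k, ho, wo))
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
        return cols.reshape(n, c * k * k, ho * wo), ho, wo

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, ho, wo = self._cols(x)
        self._x_shape, self._cols_cache = x.shape, cols
        out = np.einsum("oc,ncl->nol", self.W, cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, ho, wo = grad.shape
        g = grad.reshape(n, self.cout, ho * wo)
        self.gW[...] = np.einsum("nol,ncl->oc", g, self._cols_cache)
        self.gb[...] = g.sum(axis=(0, 2))
        gcols = np.einsum("oc,nol->ncl", self.W, g).reshape(
            n, self.cin, self.k * self.k, ho, wo
        )
        h, w = self._x_shape[2], self._x_shape[3]
        k, s, p = self.k, self.stride, self.pad
        gx = np.zeros((n, self.cin, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + ho * s : s, j : j + wo * s : s] += gcols[:, :, i * k + j]
        return gx[:, :, p : p + h, p : p + w]

    def params(self):
        return [[self.W, self.gW], [self.b, self.gb]]


class DepthwiseConv2d(Layer):
    """Per-channel 3x3 spatial filtering (the depthwise half of a separable conv)."""

    def __init__(self, cin: int, k: int, stride: int, rng: np.random.Generator):
        self.W = rng.standard_normal((cin, k, k)) * np.sqrt(2.0 / (k * k))
        self.b = np.zeros(cin)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k, self.stride = k, stride
        self.pad = k // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = _pad(x, p)
        self._xp, self._x_shape = xp, x.shape
        out = np.zeros((n, c, ho, wo))
        for i in range(k):
            for j in range(k):
                out += self.W[None, :, i, j, None, None] * xp[
                    :, :, i : i + ho * s : s, j : j + wo * s : s
                ]
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, ho, wo = grad.shape
        k, s, p = self.k, self.stride, self.pad
        h, w = self._x_shape[2], self._x_shape[3]
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                patch = self._xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
                self.gW[:, i, j] = (grad * patch).sum(axis=(0, 2, 3))
                gx[:, :, i : i + ho * s : s, j : j + wo * s : s] += (
                    self.W[None, :, i, j, None, None] * grad
                )
        self.gb[...] = grad.sum(axis=(0, 2, 3))
        return gx[:, :, p : p + h, p : p + w]

    def params(self):
        return [[self.W, self.gW], [self.b, self.gb]]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.ggamma[...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma[None, :, None, None]
        if not self._train:
            return gxhat / self._std[None, :, None, None]
        m = self._m
        term = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (gxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term / self._std[None, :, None, None]

    def params(self):
        return [[self.gamma, self.ggamma], [self.beta, self.gbeta]]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2, stride 2, ceil mode (odd edges padded) to match strided shortcuts."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
        ho, wo = x.shape[2] // 2, x.shape[3] // 2
        xv = x.reshape(n, c, ho, 2, wo, 2)
        out = xv.max(axis=(3, 5))
        self._mask = xv == out[:, :, :, None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, ho, wo = grad.shape
        g = self._mask * grad[:, :, :, None, :, None]
        # split ties evenly so gradients stay bounded
        g = g / self._mask.sum(axis=(3, 5), keepdims=True)
        h, w = self._x_shape[2], self._x_shape[3]
        return g.reshape(n, c, ho * 2, wo * 2)[:, :, :h, :w]


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [[self.W, self.gW], [self.b, self.gb]]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]


class Identity(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Residual(Layer):
    def __init__(self, main: Sequential, shortcut: Layer):
        self.main, self.shortcut = main, shortcut

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.main.forward(x, train) + self.shortcut.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.main.backward(grad) + self.shortcut.backward(grad)

    def params(self):
        return self.main.params() + self.shortcut.params()

    def buffers(self):
        return self.main.buffers() + self.shortcut.buffers()


def _separable(cin: int, cout: int, rng: np.random.Generator) -> list[Layer]:
    """One depthwise-separable convolution layer (depthwise 3x3 + pointwise 1x1)."""
    return [DepthwiseConv2d(cin, 3, 1, rng), Conv2d(cin, cout, 1, 1, rng)]


class SoftmaxClassifier:
    """Sequential CNN with a softmax head and Adam training."""

    def __init__(self, net: Sequential, n_classes: int, architecture: dict):
        self.net = net
        self.n_classes = n_classes
        self.architecture = architecture
        self._adam_state: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._t = 0

    # -- persistence -------------------------------------------------------
    def _state(self) -> list[np.ndarray]:
        return [p for p, _ in self.net.params()] + self.net.buffers()

    def save_weights(self, path) -> None:
        """Serialize trainable parameters and batch-norm statistics to .npz."""
        np.savez(path, *self._state())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            arrays = [data[k] for k in data.files]
        state = self._state()
        if len(arrays) != len(state):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(state, arrays):
            dst[...] = src

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities from the softmax output layer (rows sum to 1)."""
        outs = []
        for i in range(0, len(X), batch_size):
            logits = self.net.forward(X[i : i + batch_size], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- training ----------------------------------------------------------
    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        params = self.net.params()
        if self._adam_state is None:
            self._adam_state = [(np.zeros_like(p), np.zeros_like(p)) for p, _ in params]
        self._t += 1
        for (p, g), (m, v) in zip(params, self._adam_state):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        learning_rate: float,
        batch_size: int,
        rng: np.random.Generator,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> dict:
        """Minibatch Adam on softmax cross-entropy; returns the training history."""
        if len(X) == 0:
            raise ValueError("empty training set")
        history: dict[str, list[float]] = {"loss": [], "val_accuracy": []}
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = X[idx], y[idx]
                logits = self.net.forward(xb, train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                probs = e / e.sum(axis=1, keepdims=True)
                losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()))
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                self.net.backward(grad / len(yb))
                self._adam_step(learning_rate)
            history["loss"].append(float(np.mean(losses)))
            if X_val is not None and len(X_val):
                history["val_accuracy"].append(float((self.predict(X_val) == y_val).mean()))
        return history


def build_model(scale: str, in_channels: int = 3, n_classes: int = 2, seed: int = 0) -> SoftmaxClassifier:
    """Construct the mini or full depthwise-separable CNN.

    The full scale packs 3 standard convolutions (the stem module) and 33
    separable convolutions into 14 residual modules; the mini scale keeps one
    stem convolution and 2 separable residual modules and accepts tiny native
    input sizes.
    """
    rng = np.random.default_rng(seed)
    standard = separable = modules = shortcuts = 0
    layers: list[Layer] = []

    def sep_block(cin: int, cout: int, n_sep: int, downsample: bool) -> Residual:
        nonlocal shortcuts, separable
        main: list[Layer] = []
        c = cin
        for i in range(n_sep):
            main += _separable(c, cout, rng)
            main.append(BatchNorm2d(cout))
            if i < n_sep - 1:
                main.append(ReLU())
            c = cout
            separable += 1
        shortcut: Layer
        if downsample:
            main.append(MaxPool2d())
            shortcut = Sequential([Conv2d(cin, cout, 1, 2, rng), BatchNorm2d(cout)])
            shortcuts += 1
        elif cin != cout:
            shortcut = Sequential([Conv2d(cin, cout, 1, 1, rng), BatchNorm2d(cout)])
            shortcuts += 1
        else:
            shortcut = Identity()
        return Residual(Sequential(main), shortcut)

    if scale == "mini":
        layers += [Conv2d(in_channels, 8, 3, 1, rng), BatchNorm2d(8), ReLU()]
        standard += 1
        for cin, cout in ((8, 16), (16, 32)):
            layers += [sep_block(cin, cout, 2, downsample=True), ReLU()]
            modules += 1
        head_in = 32
    elif scale == "full":
        # module 1: the stem of 3 standard convolutions
        layers += [
            Conv2d(in_channels, 16, 3, 2, rng), BatchNorm2d(16), ReLU(),
            Conv2d(16, 32, 3, 1, rng), BatchNorm2d(32), ReLU(),
            Conv2d(32, 32, 1, 1, rng), BatchNorm2d(32), ReLU(),
        ]
        standard += 3
        modules += 1
        # modules 2-4: entry blocks, 2 separable convs each, downsampling
        c = 32
        for cout in (32, 64, 64):
            layers += [sep_block(c, cout, 2, downsample=True), ReLU()]
            modules += 1
            c = cout
        # modules 5-12: middle blocks, 3 separable convs each, identity shortcuts
        for _ in range(8):
            layers += [sep_block(c, c, 3, downsample=False), ReLU()]
            modules += 1
        # module 13: exit block with 2 separable convs
        layers += [sep_block(c, 96, 2, downsample=True), ReLU()]
        modules += 1
        c = 96
        # module 14: final separable conv ahead of the pooled softmax head
        layers += _separable(c, 128, rng) + [BatchNorm2d(128), ReLU()]
        separable += 1
        modules += 1
        head_in = 128
    else:
        raise ValueError(f"unknown scale {scale!r}")

    # 1x1 shortcut projections are bookkept separately from the stem convolutions
    arch = {
        "scale": scale,
        "modules": modules,
        "standard_convs": standard,
        "separable_convs": separable,
        "shortcut_projections": shortcuts,
    }
    layers += [GlobalAvgPool(), Dense(head_in, n_classes, rng)]
    return SoftmaxClassifier(Sequential(layers), n_classes, arch)
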