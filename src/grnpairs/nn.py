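"""Minimal NumPy neural-network engine.

Implements exactly the layers the image-pair classifier needs — 2-D
convolution, batch normalization, max / global-average pooling, fully
connected layers, dropout and the usual activations — with hand-written
backward passes and a plain SGD optimizer.  Convolutions run as im2col +
matmul so the heavy lifting happens inside BLAS.

Conventions
-----------
* Tensors are ``float32`` NCHW arrays (``float64`` works too; layers follow
  the input dtype, which the gradient-check tests rely on).
* Every layer exposes ``forward(x, training)`` and ``backward(grad_out)``;
  ``backward`` accumulates parameter gradients into ``layer.grads`` and
  returns the gradient w.r.t. its input.
* All randomness (weight init, dropout masks) flows from a single
  ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "BatchNorm1d", "MaxPool2d",
    "GlobalAvgPool2d", "Flatten", "Linear", "ReLU", "Tanh", "Sigmoid",
    "Dropout", "Sequential", "Bottleneck", "Network", "SGD",
    "sigmoid", "bce_with_logits", "bce_with_logits_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed from logits for stability."""
    z = logits.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    # softplus(z) - y*z, with softplus(z) = max(z,0) + log1p(exp(-|z|))
    loss = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def bce_with_logits_grad(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits)."""
    p = sigmoid(logits.astype(np.float64))
    g = (p - y.reshape(p.shape)) / p.size
    return g.astype(logits.dtype)


class Layer:
    """Base layer: parameter-free, shape-preserving by default."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def state(self) -> dict[str, np.ndarray]:
        """Arrays to persist (parameters plus any running statistics)."""
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k in self.params:
                self.params[k] = v.copy()


def _windows(xpad: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp,kh,kw) sliding windows of a padded NCHW tensor."""
    win = np.lib.stride_tricks.sliding_window_view(xpad, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int | tuple[int, int],
                 stride: int = 1, pad: int | tuple[int, int] = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        ph, pw = (pad, pad) if isinstance(pad, int) else pad
        self.kh, self.kw, self.sh, self.sw, self.ph, self.pw = kh, kw, stride, stride, ph, pw
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))
        self.params["w"] = w.astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"Conv2d expected {self.in_ch} input channels, got {C}")
        Hp = (H + 2 * self.ph - self.kh) // self.sh + 1
        Wp = (W + 2 * self.pw - self.kw) // self.sw + 1
        if Hp < 1 or Wp < 1:
            raise ValueError(
                f"Conv2d kernel {self.kh}x{self.kw} stride {self.sh} does not fit "
                f"input {H}x{W} (pad {self.ph},{self.pw})")
        xpad = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        cols = _windows(xpad, self.kh, self.kw, self.sh, self.sw)  # N,C,Hp,Wp,kh,kw
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Hp * Wp, -1)
        wmat = self.params["w"].reshape(self.out_ch, -1).astype(x.dtype)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"].astype(x.dtype)
        self._cache = (x.shape, xpad.shape, cols, x.dtype)
        return out.reshape(N, Hp, Wp, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        (xshape, padshape, cols, dtype) = self._cache
        N, C, H, W = xshape
        _, oc, Hp, Wp = gout.shape
        g2 = gout.transpose(0, 2, 3, 1).reshape(-1, oc)
        wmat = self.params["w"].reshape(self.out_ch, -1).astype(dtype)
        self.grads["w"] = self.grads["w"] + (g2.T @ cols).reshape(self.params["w"].shape)
        if "b" in self.params:
            self.grads["b"] = self.grads["b"] + g2.sum(axis=0)
        gcols = (g2 @ wmat).reshape(N, Hp, Wp, C, self.kh, self.kw)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Hp,Wp,kh,kw
        gpad = np.zeros(padshape, dtype=dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                gpad[:, :, i:i + self.sh * Hp:self.sh,
                     j:j + self.sw * Wp:self.sw] += gcols[:, :, :, :, i, j]
        if self.ph or self.pw:
            gpad = gpad[:, :, self.ph:self.ph + H, self.pw:self.pw + W]
        return gpad


class _BatchNorm(Layer):
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.n, self.momentum, self.eps = n, momentum, eps
        self.params["gamma"] = np.ones(n, dtype=np.float32)
        self.params["beta"] = np.zeros(n, dtype=np.float32)
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)
        self.zero_grad()

    # subclasses set self._axes (reduction axes) and self._shape (broadcast shape)
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        shape = self._bshape(x)
        if training:
            mu = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, training, x.dtype)
        return (self.params["gamma"].reshape(shape).astype(x.dtype) * xhat
                + self.params["beta"].reshape(shape).astype(x.dtype))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, training, dtype = self._cache
        shape = self._bshape(gout)
        self.grads["gamma"] = self.grads["gamma"] + (gout * xhat).sum(axis=self._axes)
        self.grads["beta"] = self.grads["beta"] + gout.sum(axis=self._axes)
        gxhat = gout * self.params["gamma"].reshape(shape).astype(dtype)
        if not training:
            return gxhat * inv.reshape(shape)
        m = xhat.size // xhat.shape[self._ch_axis]
        gx = (gxhat
              - gxhat.mean(axis=self._axes, keepdims=True)
              - xhat * (gxhat * xhat).sum(axis=self._axes, keepdims=True) / m)
        return gx * inv.reshape(shape)

    def state(self) -> dict[str, np.ndarray]:
        s = dict(self.params)
        s["running_mean"] = self.running_mean
        s["running_var"] = self.running_var
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        if "running_mean" in state:
            self.running_mean = state["running_mean"].copy()
            self.running_var = state["running_var"].copy()


class BatchNorm2d(_BatchNorm):
    _axes = (0, 2, 3)
    _ch_axis = 1

    def _bshape(self, x):
        return (1, self.n, 1, 1)


class BatchNorm1d(_BatchNorm):
    _axes = (0,)
    _ch_axis = 1

    def _bshape(self, x):
        return (1, self.n)


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        super().__init__()
        self.k = kernel
        self.s = stride if stride is not None else kernel
        self.p = pad

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if self.p:
            xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)),
                        constant_values=-np.inf)
        else:
            xp = x
        win = _windows(xp, self.k, self.k, self.s, self.s)  # N,C,Hp,Wp,k,k
        flat = win.reshape(*win.shape[:4], -1)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, idx, x.dtype)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xshape, padshape, idx, dtype = self._cache
        N, C, H, W = xshape
        Hp, Wp = idx.shape[2], idx.shape[3]
        gpad = np.zeros(padshape, dtype=dtype)
        ih, iw = np.divmod(idx, self.k)
        n, c, oh, ow = np.indices(idx.shape, sparse=False)
        rows = oh * self.s + ih
        cols = ow * self.s + iw
        np.add.at(gpad, (n, c, rows, cols), gout)
        if self.p:
            gpad = gpad[:, :, self.p:self.p + H, self.p:self.p + W]
        return gpad


class GlobalMaxPool2d(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        flat = x.reshape(N, C, -1)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx, x.dtype)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        shape, idx, dtype = self._cache
        N, C, H, W = shape
        gflat = np.zeros((N, C, H * W), dtype=dtype)
        np.put_along_axis(gflat, idx[..., None], gout[..., None], axis=-1)
        return gflat.reshape(shape)


class GlobalAvgPool2d(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._cache
        return np.broadcast_to(gout[:, :, None, None], (N, C, H, W)) / (H * W)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._cache)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.params["w"] = w.astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["w"].T.astype(x.dtype) + self.params["b"].astype(x.dtype)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["w"] = self.grads["w"] + gout.T @ x
        self.grads["b"] = self.grads["b"] + gout.sum(axis=0)
        return gout @ self.params["w"].astype(x.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Tanh(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * (1.0 - self._out ** 2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._out = sigmoid(x)
        return self._out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0,1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            gout = lyr.backward(gout)
        return gout

    def walk(self):
        for lyr in self.layers:
            if isinstance(lyr, (Sequential, Bottleneck)):
                yield from lyr.walk()
            else:
                yield lyr

    def zero_grad(self) -> None:
        for lyr in self.walk():
            lyr.zero_grad()


class Bottleneck(Layer):
    """ResNet v1 bottleneck: 1x1 -> 3x3 -> 1x1 with identity/projection shortcut."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.body = Sequential(
            Conv2d(in_ch, mid_ch, 1, stride=1, bias=False, rng=rng),
            BatchNorm2d(mid_ch), ReLU(),
            Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, bias=False, rng=rng),
            BatchNorm2d(mid_ch), ReLU(),
            Conv2d(mid_ch, out_ch, 1, stride=1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.short: Sequential | None = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.short = None
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b = self.body.forward(x, training)
        s = self.short.forward(x, training) if self.short is not None else x
        return self.relu.forward(b + s, training)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu.backward(gout)
        gb = self.body.backward(g)
        gs = self.short.backward(g) if self.short is not None else g
        return gb + gs

    def walk(self):
        yield from self.body.walk()
        if self.short is not None:
            yield from self.short.walk()
        yield self.relu

    def zero_grad(self) -> None:
        for lyr in self.walk():
            lyr.zero_grad()


class Network:
    """A Sequential with train/eval mode, (de)serialization and parameter access."""

    def __init__(self, seq: Sequential, meta: dict | None = None):
        self.seq = seq
        self.training = False
        self.meta = meta or {}

    def train(self) -> "Network":
        self.training = True
        return self

    def eval(self) -> "Network":
        self.training = False
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.seq.forward(x, self.training)

    __call__ = forward

    def layers(self):
        return list(self.seq.walk())

    def parameters(self, trainable_only: bool = False):
        """Yields (layer, name) for every parameter array."""
        for lyr in self.seq.walk():
            if trainable_only and lyr.frozen:
                continue
            for name in lyr.params:
                yield lyr, name

    def zero_grad(self) -> None:
        self.seq.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for lyr in self.seq.walk():
            s = lyr.state()
            for k in sorted(s):
                out.append(s[k])
        return out

    def save(self, path) -> None:
        arrays = {}
        for i, lyr in enumerate(self.seq.walk()):
            for k, v in lyr.state().items():
                arrays[f"{i}.{k}"] = v
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        for i, lyr in enumerate(self.seq.walk()):
            state = {k.split(".", 1)[1]: data[k] for k in data.files
                     if k.split(".", 1)[0] == str(i)}
            lyr.load_state(state)

    def copy_state(self) -> dict:
        return {i: {k: v.copy() for k, v in lyr.state().items()}
                for i, lyr in enumerate(self.seq.walk())}

    def load_state(self, snap: dict) -> None:
        for i, lyr in enumerate(self.seq.walk()):
            lyr.load_state(snap[i])


class SGD:
    """Plain SGD with optional momentum, over a Network's trainable parameters."""

    def __init__(self, net: Network, lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for i, lyr in enumerate(self.net.seq.walk()):
            if lyr.frozen:
                continue
            for name, p in lyr.params.items():
                g = lyr.grads[name].astype(p.dtype)
                if self.momentum:
                    v = self._vel.setdefault((i, name), np.zeros_like(p))
                    v *= self.momentum
                    v -= self.lr * g
                    p += v
                else:
                    p -= self.lr * g

    def zero_grad(self) -> None:
        self.net.zero_grad()
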