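"""Minimal layer framework with manual backpropagation, NumPy only.

Every :class:`Module` implements ``forward`` (caching what backward needs)
and ``backward`` (returning the input gradient and accumulating parameter
gradients).  Containers propagate an optional :class:`Tap` that captures the
activation and output-gradient of one named layer — the hook GradCAM uses.

Arrays are float32 by default; :func:`set_dtype` switches to float64 for
numerical gradient checking.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Tap:
    """Capture point for one named layer's activation and output gradient."""

    def __init__(self, layer_name: str):
        self.layer_name = layer_name
        self.activation: np.ndarray | None = None
        self.grad: np.ndarray | None = None


class Module:
    name: str = ""

    def __init__(self, name: str = ""):
        self.name = name
        self.training = False

    # -- plumbing ----------------------------------------------------------
    def __call__(self, x, tap: Tap | None = None):
        out = self.forward(x, tap)
        if tap is not None and self.name == tap.layer_name:
            tap.activation = out
        return out

    def back(self, dout, tap: Tap | None = None):
        if tap is not None and self.name == tap.layer_name:
            tap.grad = dout
        return self.backward(dout, tap)

    # -- to implement ------------------------------------------------------
    def forward(self, x, tap=None):
        raise NotImplementedError

    def backward(self, dout, tap=None):
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return [p for c in self.children() for p in c.parameters()]

    def children(self) -> list["Module"]:
        return []

    def describe(self) -> dict:
        return {"type": type(self).__name__, "name": self.name}

    # -- shared helpers ----------------------------------------------------
    def set_training(self, mode: bool) -> None:
        self.training = mode
        for c in self.children():
            c.set_training(mode)

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng
        for c in self.children():
            c.set_rng(rng)

    def named_modules(self, out=None) -> dict[str, "Module"]:
        if out is None:
            out = {}
        if self.name:
            out[self.name] = self
        for c in self.children():
            c.named_modules(out)
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for c in self.children():
            out.extend(c.modules())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All learned/running arrays, in a stable order (for checkpoints)."""
        arrs = [p.value for p in self.parameters()]
        for m in self.modules():
            for attr in ("running_mean", "running_var"):
                a = getattr(m, attr, None)
                if a is not None:
                    arrs.append(a)
        return arrs


class Sequential(Module):
    def __init__(self, layers, name: str = ""):
        super().__init__(name)
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x, tap=None):
        for layer in self.layers:
            x = layer(x, tap)
        return x

    def backward(self, dout, tap=None):
        for layer in reversed(self.layers):
            dout = layer.back(dout, tap)
        return dout

    def describe(self):
        return {"type": "Sequential", "name": self.name,
                "layers": [l.describe() for l in self.layers]}


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


class Conv1d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 rng=None, name=""):
        super().__init__(name)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel))
        self.b = Param(np.zeros(out_ch))

    def parameters(self):
        return [self.w, self.b]

    def out_length(self, L):
        return (L + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x, tap=None):
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        N, C, L = x.shape
        if L < self.kernel:
            raise ValueError(
                f"{self.name or 'conv1d'}: input length {L} shorter than "
                f"kernel {self.kernel}")
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C, Lo, K)
        Lo = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(N, Lo, C * self.kernel)
        self._cache = (cols, x.shape, Lo)
        out = cols @ self.w.value.reshape(self.out_ch, -1).T + self.b.value
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dout, tap=None):
        cols, xshape, Lo = self._cache
        N, C, Lpad = xshape
        d = dout.transpose(0, 2, 1)  # (N, Lo, Co)
        self.w.grad += (
            d.reshape(-1, self.out_ch).T @ cols.reshape(-1, C * self.kernel)
        ).reshape(self.w.value.shape)
        self.b.grad += d.sum(axis=(0, 1))
        dcols = d @ self.w.value.reshape(self.out_ch, -1)  # (N, Lo, C*K)
        dcols = dcols.reshape(N, Lo, C, self.kernel).transpose(0, 2, 1, 3)
        dx = np.zeros(xshape, dtype=dout.dtype)
        idx = self.stride * np.arange(Lo)
        for k in range(self.kernel):
            dx[:, :, idx + k] += dcols[:, :, :, k]
        if self.padding:
            dx = dx[:, :, self.padding : Lpad - self.padding]
        self._cache = None
        return dx

    def describe(self):
        return {"type": "Conv1d", "name": self.name, "in_channels": self.in_ch,
                "out_channels": self.out_ch, "kernel": self.kernel,
                "stride": self.stride, "padding": self.padding}


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 rng=None, name=""):
        super().__init__(name)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel),
                                in_ch * kernel * kernel))
        self.b = Param(np.zeros(out_ch))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, tap=None):
        p, k, s = self.padding, self.kernel, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        N, C, H, W = x.shape
        if H < k or W < k:
            raise ValueError(f"{self.name or 'conv2d'}: input {H}x{W} smaller "
                             f"than kernel {k}")
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s, :, :]  # (N, C, Ho, Wo, k, k)
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * k * k)
        self._cache = (cols, x.shape, Ho, Wo)
        out = cols @ self.w.value.reshape(self.out_ch, -1).T + self.b.value
        return np.ascontiguousarray(
            out.reshape(N, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dout, tap=None):
        cols, xshape, Ho, Wo = self._cache
        N, C, Hp, Wp = xshape
        k, s, p = self.kernel, self.stride, self.padding
        d = dout.transpose(0, 2, 3, 1).reshape(N, Ho * Wo, self.out_ch)
        self.w.grad += (
            d.reshape(-1, self.out_ch).T @ cols.reshape(-1, C * k * k)
        ).reshape(self.w.value.shape)
        self.b.grad += d.sum(axis=(0, 1))
        dcols = d @ self.w.value.reshape(self.out_ch, -1)
        dcols = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(xshape, dtype=dout.dtype)
        hi = s * np.arange(Ho)
        wi = s * np.arange(Wo)
        for kh in range(k):
            for kw in range(k):
                dx[:, :, hi[:, None] + kh, wi[None, :] + kw] += dcols[:, :, :, :, kh, kw]
        if p:
            dx = dx[:, :, p : Hp - p, p : Wp - p]
        self._cache = None
        return dx

    def describe(self):
        return {"type": "Conv2d", "name": self.name, "in_channels": self.in_ch,
                "out_channels": self.out_ch, "kernel": self.kernel,
                "stride": self.stride, "padding": self.padding}


# ---------------------------------------------------------------------------
# normalisation, activation, regularisation
# ---------------------------------------------------------------------------


class BatchNorm(Module):
    """Batch normalisation over all axes but the channel axis (axis 1).

    ``momentum`` follows the running = momentum * running + (1 - momentum) *
    batch convention, so 0.99 means slowly-moving running statistics.  The
    default 0.9 suits short desk-scale runs, where running statistics must
    catch up with batch statistics within a few hundred optimiser steps.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5, name=""):
        super().__init__(name)
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def parameters(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, self.channels) + (1,) * (x.ndim - 2)

    def forward(self, x, tap=None):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * invstd.reshape(sh)
        self._cache = (xhat, invstd, axes, sh, x.shape)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dout, tap=None):
        xhat, invstd, axes, sh, xshape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        if not self.training:
            self._cache = None
            return dout * (self.gamma.value * invstd).reshape(sh)
        n = np.prod([xshape[a] for a in axes])
        dxhat = dout * self.gamma.value.reshape(sh)
        dx = (invstd.reshape(sh) / n) * (
            n * dxhat
            - dxhat.sum(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(sh)
        )
        self._cache = None
        return dx

    def describe(self):
        return {"type": "BatchNorm", "name": self.name,
                "channels": self.channels, "momentum": self.momentum}


class ReLU(Module):
    def forward(self, x, tap=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout, tap=None):
        out = dout * self._mask
        self._mask = None
        return out


class Dropout(Module):
    def __init__(self, p=0.3, name=""):
        super().__init__(name)
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(0)

    def forward(self, x, tap=None):
        if not self.training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout, tap=None):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out

    def describe(self):
        return {"type": "Dropout", "name": self.name, "p": self.p}


# ---------------------------------------------------------------------------
# pooling / reshaping
# ---------------------------------------------------------------------------


class MaxPool1d(Module):
    """Max pooling with ceil-mode padding (right-pads with -inf when the
    length is not a multiple of the stride), so deep stacks of blocks never
    collapse odd lengths to zero."""

    def __init__(self, kernel=2, stride=2, name=""):
        super().__init__(name)
        self.kernel, self.stride = kernel, stride

    def out_length(self, L):
        return max(1, -(-(L - self.kernel) // self.stride) + 1) if L >= 1 else 0

    def forward(self, x, tap=None):
        N, C, L = x.shape
        k, s = self.kernel, self.stride
        Lo = self.out_length(L)
        need = (Lo - 1) * s + k
        if need > L:
            x = np.pad(x, ((0, 0), (0, 0), (0, need - L)),
                       constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        arg = win.argmax(axis=3)
        self._cache = (arg, (N, C, L), Lo)
        return np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def backward(self, dout, tap=None):
        arg, xshape, Lo = self._cache
        N, C, L = xshape
        dx = np.zeros((N, C, L + max(0, (Lo - 1) * self.stride + self.kernel - L)),
                      dtype=dout.dtype)
        pos = arg + self.stride * np.arange(Lo)[None, None, :]
        np.add.at(dx.reshape(N * C, -1),
                  (np.repeat(np.arange(N * C), Lo), pos.reshape(N * C, Lo).ravel()),
                  dout.reshape(N * C, Lo).ravel())
        self._cache = None
        return dx[:, :, :L]

    def describe(self):
        return {"type": "MaxPool1d", "name": self.name,
                "kernel": self.kernel, "stride": self.stride}


class AvgPool1d(Module):
    """Average pooling; kernel 1 with stride 2 is plain subsampling."""

    def __init__(self, kernel=1, stride=2, name=""):
        super().__init__(name)
        self.kernel, self.stride = kernel, stride

    def forward(self, x, tap=None):
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        self._cache = (x.shape, win.shape[2])
        return win.mean(axis=3)

    def backward(self, dout, tap=None):
        xshape, Lo = self._cache
        dx = np.zeros(xshape, dtype=dout.dtype)
        idx = self.stride * np.arange(Lo)
        for k in range(self.kernel):
            dx[:, :, idx + k] += dout / self.kernel
        self._cache = None
        return dx

    def describe(self):
        return {"type": "AvgPool1d", "name": self.name,
                "kernel": self.kernel, "stride": self.stride}


class MaxPool2d(Module):
    def __init__(self, kernel=2, stride=2, name=""):
        super().__init__(name)
        self.kernel, self.stride = kernel, stride

    def forward(self, x, tap=None):
        N, C, H, W = x.shape
        k, s = self.kernel, self.stride
        Ho = max(1, -(-(H - k) // s) + 1)
        Wo = max(1, -(-(W - k) // s) + 1)
        needH, needW = (Ho - 1) * s + k, (Wo - 1) * s + k
        if needH > H or needW > W:
            x = np.pad(x, ((0, 0), (0, 0), (0, max(0, needH - H)),
                           (0, max(0, needW - W))), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s, :, :]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=4)
        self._cache = ((N, C, H, W), x.shape, arg, Ho, Wo)
        return np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]

    def backward(self, dout, tap=None):
        orig, padded, arg, Ho, Wo = self._cache
        N, C, H, W = orig
        k, s = self.kernel, self.stride
        dx = np.zeros(padded, dtype=dout.dtype)
        hpos = arg // k + s * np.arange(Ho)[None, None, :, None]
        wpos = arg % k + s * np.arange(Wo)[None, None, None, :]
        flatpos = hpos * padded[3] + wpos
        np.add.at(dx.reshape(N * C, -1),
                  (np.repeat(np.arange(N * C), Ho * Wo),
                   flatpos.reshape(N * C, -1).ravel()),
                  dout.reshape(N * C, -1).ravel())
        self._cache = None
        return dx[:, :, :H, :W]

    def describe(self):
        return {"type": "MaxPool2d", "name": self.name,
                "kernel": self.kernel, "stride": self.stride}


class AvgPool2d(Module):
    def __init__(self, kernel=2, stride=2, name=""):
        super().__init__(name)
        self.kernel, self.stride = kernel, stride

    def forward(self, x, tap=None):
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s, :, :]
        self._cache = (x.shape, win.shape[2], win.shape[3])
        return win.mean(axis=(4, 5))

    def backward(self, dout, tap=None):
        xshape, Ho, Wo = self._cache
        k, s = self.kernel, self.stride
        dx = np.zeros(xshape, dtype=dout.dtype)
        hi = s * np.arange(Ho)
        wi = s * np.arange(Wo)
        for kh in range(k):
            for kw in range(k):
                dx[:, :, hi[:, None] + kh, wi[None, :] + kw] += dout / (k * k)
        self._cache = None
        return dx

    def describe(self):
        return {"type": "AvgPool2d", "name": self.name,
                "kernel": self.kernel, "stride": self.stride}


class GlobalAvgPool(Module):
    """Mean over all spatial axes -> (N, C)."""

    def forward(self, x, tap=None):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout, tap=None):
        sh = self._shape
        n = int(np.prod(sh[2:]))
        return np.broadcast_to(
            dout.reshape(sh[:2] + (1,) * (len(sh) - 2)), sh
        ).copy() / n


class Flatten(Module):
    def forward(self, x, tap=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, tap=None):
        return dout.reshape(self._shape)


class Linear(Module):
    """Fully-connected layer.  ``init_scale`` shrinks the He initialisation;
    classifier heads use a small scale so untrained networks emit
    near-uniform class probabilities."""

    def __init__(self, in_features, out_features, rng=None, name="",
                 init_scale=1.0):
        super().__init__(name)
        self.in_features, self.out_features = in_features, out_features
        rng = rng or np.random.default_rng(0)
        self.w = Param(init_scale
                       * _he_init(rng, (out_features, in_features), in_features))
        self.b = Param(np.zeros(out_features))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, tap=None):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout, tap=None):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.w.value
        self._x = None
        return dx

    def describe(self):
        return {"type": "Linear", "name": self.name,
                "in_features": self.in_features,
                "out_features": self.out_features}


class DualPoolConcat1d(Module):
    """Concatenation of global average- and max-pooled features -> (N, 2C)."""

    def forward(self, x, tap=None):
        self._shape = x.shape
        self._arg = x.argmax(axis=2)
        avg = x.mean(axis=2)
        mx = np.take_along_axis(x, self._arg[..., None], axis=2)[..., 0]
        return np.concatenate([avg, mx], axis=1)

    def backward(self, dout, tap=None):
        N, C, L = self._shape
        davg, dmax = dout[:, :C], dout[:, C:]
        dx = np.broadcast_to(davg[:, :, None], self._shape).copy() / L
        np.add.at(dx.reshape(N * C, L),
                  (np.arange(N * C), self._arg.ravel()), dmax.ravel())
        self._shape = self._arg = None
        return dx

    def describe(self):
        return {"type": "DualPoolConcat1d", "name": self.name,
                "pools": ["avg", "max"]}
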