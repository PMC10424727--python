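"""Network container, losses and the Adam optimiser."""

from __future__ import annotations

import numpy as np

from .core import Module, Tap, get_dtype


class Network:
    """A root module plus the bookkeeping training needs."""

    def __init__(self, root: Module, n_classes: int, mode: str = "multiclass"):
        if mode not in ("multiclass", "multilabel"):
            raise ValueError(f"unknown mode {mode!r}")
        self.root = root
        self.n_classes = n_classes
        self.mode = mode

    def forward(self, x, training: bool = False, tap: Tap | None = None):
        self.root.set_training(training)
        return self.root(np.asarray(x, dtype=get_dtype()), tap)

    def backward(self, dlogits, tap: Tap | None = None):
        return self.root.back(dlogits, tap)

    def parameters(self):
        return self.root.parameters()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def predict_proba(self, x, batch_size: int = 32):
        """Class scores in eval mode: softmax rows (multiclass) or
        independent sigmoids (multilabel)."""
        x = np.asarray(x, dtype=get_dtype())
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            outs.append(softmax(logits) if self.mode == "multiclass"
                        else sigmoid(logits))
        return np.concatenate(outs, axis=0)

    def describe(self) -> dict:
        return {"n_classes": self.n_classes, "mode": self.mode,
                "root": self.root.describe()}

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"arr_{i}": a for i, a in enumerate(self.root.state_arrays())}

    def load_state_dict(self, state: dict) -> None:
        arrays = self.root.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("checkpoint does not match architecture")
        for i, a in enumerate(arrays):
            a[...] = state[f"arr_{i}"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.root.state_arrays()]

    def restore(self, snap) -> None:
        for a, s in zip(self.root.state_arrays(), snap):
            a[...] = s


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def softmax_ce_loss(logits, y_idx):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), y_idx] + 1e-12))
    d = p
    d[np.arange(n), y_idx] -= 1.0
    return float(loss), (d / n).astype(logits.dtype)


def bce_logits_loss(logits, y):
    """Mean per-class binary cross-entropy; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = np.mean(np.clip(z, 0, None) - z * y + np.log1p(np.exp(-np.abs(z))))
    d = (sigmoid(z) - y) / z.size
    return float(loss), d.astype(logits.dtype)


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
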