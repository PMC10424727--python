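"""Classifier architectures and training for the three model tracks.

* ``cnn1d``    — 12 plain convolutional blocks (conv -> batch-norm -> ReLU ->
  max-pool -> dropout) on the differenced, z-scored raw signal; channels
  taper 256 -> 32 and kernels follow the schedule [20, 5x5, 3x6].
* ``resnet1d`` — a kernel-15 / 64-channel stem followed by four residual
  blocks and a concatenated average+max global-pooling head.
* ``image2d``  — standard ResNet50 / DenseNet121 image classifiers, trained
  from scratch on rasterized Poincare diagrams, with the final layer sized
  to the class count.

All models accept a ``width_scale`` (and the 2D models a ``depth_scale``)
so desk-scale experiments can shrink capacity without touching the layout;
the canonical schedules are the defaults.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .io import EcgRecord
from .poincare import build_points, rasterize, to_model_input
from .preprocess import nn_series, prepare_window, transform_1d

logger = logging.getLogger(__name__)

CNN1D_CHANNELS = [256, 256, 128, 128, 128, 64, 64, 64, 64, 32, 32, 32]
CNN1D_KERNELS = [20] + [5] * 5 + [3] * 6
RESNET1D_STEM_KERNEL = 15
RESNET1D_STEM_CHANNELS = 64
#: Residual-block widths rising from the stem's 64 channels to 256.
RESNET1D_BLOCK_CHANNELS = [64, 128, 192, 256]
RESNET1D_BLOCK_KERNEL = 7


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    lr: float = 3e-3
    patience: int = 10
    min_epochs: int = 15  # early stopping disabled before this epoch
    seed: int = 0
    verbose: bool = False


@dataclass
class ModelBundle:
    """Architecture + weights + the input transform the model expects."""

    arch: str
    net: nn.Network
    classes: list[str]
    input_kind: str  # "signal1d" or "poincare"
    config: dict = field(default_factory=dict)
    trained: bool = False
    history: list = field(default_factory=list)

    @property
    def mode(self) -> str:
        return self.net.mode

    def describe(self) -> dict:
        d = self.net.describe()
        d.update(arch=self.arch, classes=self.classes,
                 input_kind=self.input_kind, config=self.config)
        return d

    def dump_description(self, path) -> None:
        Path(path).write_text(json.dumps(self.describe(), indent=1))

    def save_weights(self, path) -> None:
        self.net.save(path)

    def load_weights(self, path) -> None:
        self.net.load(path)
        self.trained = True


# ---------------------------------------------------------------------------
# composite blocks
# ---------------------------------------------------------------------------


class ResBlock1d(nn.Module):
    """conv -> BN -> ReLU -> dropout -> conv -> BN, plus the residual input,
    then ReLU.  A kernel-1 projection aligns the residual when the channel
    count or stride changes."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, dropout=0.3,
                 rng=None, name=""):
        super().__init__(name)
        pad = kernel // 2
        self.conv1 = nn.Conv1d(in_ch, out_ch, kernel, stride=stride,
                               padding=pad, rng=rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm(out_ch, name=f"{name}.bn1")
        self.relu1 = nn.ReLU(name=f"{name}.relu1")
        self.drop = nn.Dropout(dropout, name=f"{name}.drop")
        self.conv2 = nn.Conv1d(out_ch, out_ch, kernel, padding=pad,
                               rng=rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm(out_ch, name=f"{name}.bn2")
        self.proj = None
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng,
                                  name=f"{name}.proj")
        self.relu_out = nn.ReLU(name=f"{name}.relu_out")

    def children(self):
        out = [self.conv1, self.bn1, self.relu1, self.drop, self.conv2,
               self.bn2, self.relu_out]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, tap=None):
        main = self.conv1(x, tap)
        main = self.bn1(main, tap)
        main = self.relu1(main, tap)
        main = self.drop(main, tap)
        main = self.conv2(main, tap)
        main = self.bn2(main, tap)
        skip = self.proj(x, tap) if self.proj is not None else x
        # align ceil-mode length mismatches never occur: conv padding keeps
        # main and skip the same length for any input
        return self.relu_out(main + skip, tap)

    def backward(self, dout, tap=None):
        d = self.relu_out.back(dout, tap)
        dmain = self.bn2.back(d, tap)
        dmain = self.conv2.back(dmain, tap)
        dmain = self.drop.back(dmain, tap)
        dmain = self.relu1.back(dmain, tap)
        dmain = self.bn1.back(dmain, tap)
        dmain = self.conv1.back(dmain, tap)
        dskip = self.proj.back(d, tap) if self.proj is not None else d
        return dmain + dskip

    def describe(self):
        return {
            "type": "ResBlock1d", "name": self.name,
            "layout": "conv-bn-relu-dropout-conv-bn + residual, relu",
            "channels": self.conv1.out_ch, "kernel": self.conv1.kernel,
            "stride": self.conv1.stride,
            "projection": self.proj is not None,
        }


class DenseLayer2d(nn.Module):
    """BN -> ReLU -> 1x1 conv (bottleneck) -> BN -> ReLU -> 3x3 conv, output
    concatenated onto the input (DenseNet connectivity)."""

    def __init__(self, in_ch, growth, rng=None, name=""):
        super().__init__(name)
        inter = 4 * growth
        self.bn1 = nn.BatchNorm(in_ch, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(in_ch, inter, 1, rng=rng, name=f"{name}.conv1")
        self.bn2 = nn.BatchNorm(inter, name=f"{name}.bn2")
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(inter, growth, 3, padding=1, rng=rng,
                               name=f"{name}.conv2")
        self.in_ch, self.growth = in_ch, growth

    def children(self):
        return [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2,
                self.conv2]

    def forward(self, x, tap=None):
        h = self.bn1(x, tap)
        h = self.relu1(h, tap)
        h = self.conv1(h, tap)
        h = self.bn2(h, tap)
        h = self.relu2(h, tap)
        h = self.conv2(h, tap)
        return np.concatenate([x, h], axis=1)

    def backward(self, dout, tap=None):
        dx, dh = dout[:, : self.in_ch], dout[:, self.in_ch :]
        d = self.conv2.back(np.ascontiguousarray(dh), tap)
        d = self.relu2.back(d, tap)
        d = self.bn2.back(d, tap)
        d = self.conv1.back(d, tap)
        d = self.relu1.back(d, tap)
        d = self.bn1.back(d, tap)
        return np.ascontiguousarray(dx) + d

    def describe(self):
        return {"type": "DenseLayer2d", "name": self.name,
                "in_channels": self.in_ch, "growth": self.growth}


class Bottleneck2d(nn.Module):
    """ResNet bottleneck: 1x1 -> 3x3 (stride) -> 1x1 (4x), residual add."""

    expansion = 4

    def __init__(self, in_ch, planes, stride=1, rng=None, name=""):
        super().__init__(name)
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 1, rng=rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm(planes)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=1,
                               rng=rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm(planes)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(planes, out_ch, 1, rng=rng, name=f"{name}.conv3")
        self.bn3 = nn.BatchNorm(out_ch)
        self.proj = None
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng,
                                  name=f"{name}.proj")
        self.relu_out = nn.ReLU()
        self.planes = planes

    def children(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
               self.relu2, self.conv3, self.bn3, self.relu_out]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, tap=None):
        h = self.relu1(self.bn1(self.conv1(x, tap), tap), tap)
        h = self.relu2(self.bn2(self.conv2(h, tap), tap), tap)
        h = self.bn3(self.conv3(h, tap), tap)
        skip = self.proj(x, tap) if self.proj is not None else x
        return self.relu_out(h + skip, tap)

    def backward(self, dout, tap=None):
        d = self.relu_out.back(dout, tap)
        dm = self.conv3.back(self.bn3.back(d, tap), tap)
        dm = self.relu2.back(dm, tap)
        dm = self.conv2.back(self.bn2.back(dm, tap), tap)
        dm = self.relu1.back(dm, tap)
        dm = self.conv1.back(self.bn1.back(dm, tap), tap)
        dskip = self.proj.back(d, tap) if self.proj is not None else d
        return dm + dskip

    def describe(self):
        return {"type": "Bottleneck2d", "name": self.name,
                "planes": self.planes, "stride": self.conv2.stride,
                "projection": self.proj is not None}


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _scaled(channels, scale):
    return [max(4, int(round(c * scale))) for c in channels]


def cnn1d_forward_length(input_len: int) -> int:
    """Length after the 12 conv+pool blocks and the final subsampling pool
    (ceil-mode pooling), or -1 when the input is too short."""
    L = input_len
    for k in CNN1D_KERNELS:
        if L < k:
            return -1
        L = -(-(L - k + 1) // 2)  # conv (no pad, stride 1) then ceil-pool /2
    return -(-(L - 1 + 1) // 2)  # avg pool kernel 1 stride 2


def cnn1d_min_length() -> int:
    lo, hi = 1, 20000
    while lo < hi:
        mid = (lo + hi) // 2
        if cnn1d_forward_length(mid) >= 1:
            hi = mid
        else:
            lo = mid + 1
    return lo


def build_cnn1d(n_classes: int, n_leads: int = 1, input_len: int = 8999,
                mode: str = "multiclass", width_scale: float = 1.0,
                seed: int = 0) -> ModelBundle:
    """The 12-block plain 1D CNN on differenced, standardised raw signal."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if cnn1d_forward_length(input_len) < 1:
        raise ValueError(
            f"input_len={input_len} is below the network's minimum receptive "
            f"length {cnn1d_min_length()}")
    rng = np.random.default_rng(seed)
    chans = _scaled(CNN1D_CHANNELS, width_scale)
    layers = []
    in_ch = n_leads
    for bi, (c, k) in enumerate(zip(chans, CNN1D_KERNELS), start=1):
        layers.append(nn.Sequential([
            nn.Conv1d(in_ch, c, k, rng=rng, name=f"block{bi}.conv"),
            nn.BatchNorm(c, momentum=0.99, name=f"block{bi}.bn"),
            nn.ReLU(),
            nn.MaxPool1d(2, 2, name=f"block{bi}.pool"),
            nn.Dropout(0.3, name=f"block{bi}.drop"),
        ], name=f"block{bi}"))
        in_ch = c
    tail_len = cnn1d_forward_length(input_len)
    head = nn.Sequential([
        nn.AvgPool1d(1, 2, name="head.avgpool"),
        nn.Flatten(),
        nn.Linear(in_ch * tail_len, n_classes, rng=rng, name="head.fc", init_scale=0.1),
    ], name="head")
    root = nn.Sequential(layers + [head], name="cnn1d")
    net = nn.Network(root, n_classes, mode)
    return ModelBundle(
        arch="cnn1d", net=net, classes=[], input_kind="signal1d",
        config={"input_len": input_len, "width_scale": width_scale,
                "n_leads": n_leads, "seed": seed,
                "last_conv": "block12.conv"},
    )


def build_resnet1d(n_classes: int, n_leads: int = 1, mode: str = "multiclass",
                   width_scale: float = 1.0, seed: int = 0) -> ModelBundle:
    """The 1D ResNet: kernel-15/64-channel stem, four residual blocks, and a
    concatenated global average+max pooling head.  The global pools make the
    model length-independent."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    stem_ch = max(4, int(round(RESNET1D_STEM_CHANNELS * width_scale)))
    widths = _scaled(RESNET1D_BLOCK_CHANNELS, width_scale)
    stem = nn.Sequential([
        nn.Conv1d(n_leads, stem_ch, RESNET1D_STEM_KERNEL, stride=2,
                  padding=RESNET1D_STEM_KERNEL // 2, rng=rng,
                  name="stem.conv"),
        nn.BatchNorm(stem_ch, name="stem.bn"),
        nn.ReLU(),
        nn.MaxPool1d(2, 2, name="stem.pool"),
    ], name="stem")
    blocks = []
    in_ch = stem_ch
    for bi, w in enumerate(widths, start=1):
        stride = 1 if bi == 1 else 2
        blocks.append(ResBlock1d(in_ch, w, RESNET1D_BLOCK_KERNEL,
                                 stride=stride, rng=rng, name=f"block{bi}"))
        in_ch = w
    head = nn.Sequential([
        nn.DualPoolConcat1d(name="head.dualpool"),
        nn.Linear(2 * in_ch, n_classes, rng=rng, name="head.fc", init_scale=0.1),
    ], name="head")
    root = nn.Sequential([stem] + blocks + [head], name="resnet1d")
    net = nn.Network(root, n_classes, mode)
    return ModelBundle(
        arch="resnet1d", net=net, classes=[], input_kind="signal1d",
        config={"width_scale": width_scale, "n_leads": n_leads, "seed": seed,
                "last_conv": f"block{len(widths)}.conv2"},
    )


DENSENET121_BLOCKS = (6, 12, 24, 16)
RESNET50_BLOCKS = (3, 4, 6, 3)


def build_image2d(backbone: str, n_classes: int, mode: str = "multiclass",
                  image_size: int = 224, width_scale: float = 1.0,
                  depth_scale: float = 1.0, seed: int = 0) -> ModelBundle:
    """Standard 2D image backbones adapted to Poincare-diagram inputs.

    ``densenet121`` uses growth 32 with dense blocks (6, 12, 24, 16);
    ``resnet50`` uses bottleneck stages (3, 4, 6, 3).  ``width_scale`` and
    ``depth_scale`` shrink growth/width and per-stage depth for desk-scale
    training; 1.0 gives the canonical layouts.  Inputs are 3-channel
    ``image_size`` x ``image_size`` grids; weights are randomly initialised
    (trained from scratch).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    last_conv = ""
    if backbone == "densenet121":
        growth = max(2, int(round(32 * width_scale)))
        init_ch = 2 * growth
        layers = [
            nn.Conv2d(3, init_ch, 7, stride=2, padding=3, rng=rng,
                      name="stem.conv"),
            nn.BatchNorm(init_ch, name="stem.bn"),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, name="stem.pool"),
        ]
        ch = init_ch
        for si, n_layers in enumerate(DENSENET121_BLOCKS, start=1):
            n_layers = max(1, int(round(n_layers * depth_scale)))
            for li in range(1, n_layers + 1):
                layers.append(DenseLayer2d(ch, growth, rng=rng,
                                           name=f"dense{si}.layer{li}"))
                ch += growth
                last_conv = f"dense{si}.layer{li}.conv2"
            if si < len(DENSENET121_BLOCKS):
                out_ch = ch // 2
                layers += [
                    nn.BatchNorm(ch, name=f"trans{si}.bn"),
                    nn.ReLU(),
                    nn.Conv2d(ch, out_ch, 1, rng=rng, name=f"trans{si}.conv"),
                    nn.AvgPool2d(2, 2, name=f"trans{si}.pool"),
                ]
                ch = out_ch
        layers += [
            nn.BatchNorm(ch, name="final.bn"),
            nn.ReLU(),
            nn.GlobalAvgPool(name="final.gap"),
            nn.Linear(ch, n_classes, rng=rng, name="head.fc", init_scale=0.1),
        ]
        root = nn.Sequential(layers, name="densenet121")
    elif backbone == "resnet50":
        planes0 = max(4, int(round(64 * width_scale)))
        layers = [
            nn.Conv2d(3, planes0, 7, stride=2, padding=3, rng=rng,
                      name="stem.conv"),
            nn.BatchNorm(planes0, name="stem.bn"),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, name="stem.pool"),
        ]
        ch = planes0
        for si, n_blocks in enumerate(RESNET50_BLOCKS, start=1):
            n_blocks = max(1, int(round(n_blocks * depth_scale)))
            planes = planes0 * 2 ** (si - 1)
            for bi in range(1, n_blocks + 1):
                stride = 2 if (bi == 1 and si > 1) else 1
                layers.append(Bottleneck2d(ch, planes, stride=stride, rng=rng,
                                           name=f"stage{si}.block{bi}"))
                ch = planes * Bottleneck2d.expansion
                last_conv = f"stage{si}.block{bi}.conv3"
        layers += [
            nn.GlobalAvgPool(name="final.gap"),
            nn.Linear(ch, n_classes, rng=rng, name="head.fc", init_scale=0.1),
        ]
        root = nn.Sequential(layers, name="resnet50")
    else:
        raise ValueError(f"unknown backbone {backbone!r}; "
                         "expected 'resnet50' or 'densenet121'")
    net = nn.Network(root, n_classes, mode)
    return ModelBundle(
        arch="image2d", net=net, classes=[], input_kind="poincare",
        config={"backbone": backbone, "image_size": image_size,
                "width_scale": width_scale, "depth_scale": depth_scale,
                "seed": seed, "last_conv": last_conv},
    )


# ---------------------------------------------------------------------------
# input preparation, training, prediction
# ---------------------------------------------------------------------------


def prepare_input(bundle: ModelBundle, record: EcgRecord,
                  target_fs: float | None = None,
                  window_s: float | None = None) -> np.ndarray:
    """Apply the bundle's input transform to one record."""
    if bundle.input_kind == "signal1d":
        rec = prepare_window(record, target_fs=target_fs, window_s=window_s)
        return transform_1d(rec).x
    if bundle.input_kind == "poincare":
        nn_ivals = nn_series(record.signal[0], record.fs)
        size = bundle.config.get("image_size", 224)
        if nn_ivals.size < 2:  # unanalysable rhythm -> blank diagram
            return np.zeros((3, size, size))
        img = rasterize(build_points(nn_ivals), size=size)
        return to_model_input(img)
    raise ValueError(f"unknown input kind {bundle.input_kind!r}")


def prepare_batch(bundle: ModelBundle, records, **kw) -> np.ndarray:
    return np.stack([prepare_input(bundle, r, **kw) for r in records])


def encode_labels(classes: list[str], labels_list, mode: str) -> np.ndarray:
    if mode == "multiclass":
        idx = []
        for labels in labels_list:
            (label,) = labels if isinstance(labels, (set, frozenset, list, tuple)) \
                else (labels,)
            idx.append(classes.index(label))
        return np.asarray(idx, dtype=int)
    y = np.zeros((len(labels_list), len(classes)))
    for i, labels in enumerate(labels_list):
        for lb in labels:
            y[i, classes.index(lb)] = 1.0
    return y


def _macro_f1(y_true_idx, y_pred_idx, n_classes) -> float:
    f1s = []
    for c in range(n_classes):
        tp = np.sum((y_pred_idx == c) & (y_true_idx == c))
        fp = np.sum((y_pred_idx == c) & (y_true_idx != c))
        fn = np.sum((y_pred_idx != c) & (y_true_idx == c))
        if tp + fp + fn == 0:
            f1s.append(1.0)
        else:
            f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    return float(np.mean(f1s))


def refresh_bn_stats(net: nn.Network, X, batch_size: int = 32) -> None:
    """Re-estimate BatchNorm running statistics over ``X`` with the current
    weights (dropout off).

    Needed because slowly-moving statistics (the 12-block CNN pins momentum
    0.99) lag far behind the weights in short runs.  Setting the momentum of
    batch ``i`` to ``i / (i + 1)`` turns the exponential average into an
    arithmetic mean over all batches.
    """
    bns = [m for m in net.root.modules() if isinstance(m, nn.BatchNorm)]
    drops = [m for m in net.root.modules() if isinstance(m, nn.Dropout)]
    saved_moms = [b.momentum for b in bns]
    saved_ps = [d.p for d in drops]
    for d in drops:
        d.p = 0.0
    X = np.asarray(X, dtype=nn.get_dtype())
    for i, start in enumerate(range(0, len(X), batch_size)):
        for b in bns:
            b.momentum = i / (i + 1)
        net.forward(X[start : start + batch_size], training=True)
    for b, m in zip(bns, saved_moms):
        b.momentum = m
    for d, p in zip(drops, saved_ps):
        d.p = p


def train(bundle: ModelBundle, train_set, val_set,
          config: TrainConfig | None = None) -> ModelBundle:
    """Mini-batch Adam training with early stopping on validation macro-F1.

    ``train_set``/``val_set`` are ``(X, y)`` pairs — ``X`` stacked model
    inputs, ``y`` integer class indices (multiclass) or a binary label
    matrix (multilabel).  The weight state achieving the best validation
    macro-F1 is restored before returning.  Deterministic for a fixed seed
    up to floating-point reduction order.
    """
    config = config or TrainConfig()
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("empty training or validation set")
    net = bundle.net
    rng = np.random.default_rng(config.seed)
    net.root.set_rng(np.random.default_rng(config.seed + 1))
    opt = nn.Adam(net.parameters(), lr=config.lr)
    loss_fn = nn.softmax_ce_loss if net.mode == "multiclass" else nn.bce_logits_loss

    best_f1, best_snap, best_epoch = -1.0, net.snapshot(), -1
    X_tr = np.asarray(X_tr, dtype=nn.get_dtype())
    slow_bn = any(isinstance(m, nn.BatchNorm) and m.momentum >= 0.95
                  for m in net.root.modules())
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            logits = net.forward(X_tr[sel], training=True)
            loss, dlogits = loss_fn(logits, y_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        epoch_loss /= len(X_tr)

        if slow_bn:
            # momentum-0.99 running statistics lag the weights by hundreds of
            # steps; re-estimate them so epoch selection sees real eval scores
            refresh_bn_stats(net, X_tr, config.batch_size)
        proba = net.predict_proba(X_va, batch_size=config.batch_size)
        if net.mode == "multiclass":
            val_f1 = _macro_f1(np.asarray(y_va), proba.argmax(axis=1),
                               net.n_classes)
        else:
            pred = (proba >= 0.5).astype(int)
            f1s = []
            for c in range(net.n_classes):
                tp = np.sum((pred[:, c] == 1) & (y_va[:, c] == 1))
                fp = np.sum((pred[:, c] == 1) & (y_va[:, c] == 0))
                fn = np.sum((pred[:, c] == 0) & (y_va[:, c] == 1))
                f1s.append(2 * tp / (2 * tp + fp + fn)
                           if tp + fp + fn else 1.0)
            val_f1 = float(np.mean(f1s))
        bundle.history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_macro_f1": val_f1})
        if config.verbose:
            logger.info("epoch %d loss %.4f val macro-F1 %.4f",
                        epoch, epoch_loss, val_f1)
        if val_f1 > best_f1:
            best_f1, best_snap, best_epoch = val_f1, net.snapshot(), epoch
        elif (epoch >= config.min_epochs
              and epoch - best_epoch >= config.patience):
            break
    net.restore(best_snap)
    refresh_bn_stats(net, X_tr, config.batch_size)
    bundle.trained = True
    bundle.config["best_val_macro_f1"] = best_f1
    return bundle


def predict(bundle: ModelBundle, X, batch_size: int = 32) -> np.ndarray:
    """Per-record class scores: softmax probabilities (multiclass, rows sum
    to 1) or independent per-class probabilities (multilabel)."""
    if not bundle.trained:
        logger.warning("predicting with an untrained %s model", bundle.arch)
    return bundle.net.predict_proba(np.asarray(X), batch_size=batch_size)


def decide(bundle: ModelBundle, proba: np.ndarray, threshold: float = 0.5):
    """Decision rule: argmax for multiclass, per-class threshold for
    multilabel.  Returns a list of label sets."""
    classes = bundle.classes
    if bundle.mode == "multiclass":
        return [{classes[i]} for i in proba.argmax(axis=1)]
    out = []
    for row in proba:
        chosen = {classes[i] for i in np.flatnonzero(row >= threshold)}
        if not chosen:
            chosen = {classes[int(row.argmax())]}
        out.append(chosen)
    return out
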