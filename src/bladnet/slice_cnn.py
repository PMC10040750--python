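"""Stage-1 feature learner: a grouped 2-D CNN over slice groups, in NumPy.

Each slice group enters the network as one multi-channel 2-D image (its
slices are the channels). All convolutions are *grouped* with group count
equal to the number of slice groups, so no information crosses groups before
the per-group feature heads: three 3x3 conv blocks (batch-norm, ReLU, 2x2
max-pool), a grouped 1x1 projection to the per-group feature width, and
global average pooling. A temporary linear softmax head is attached for
supervised training and discarded afterwards; only the pooled per-group
features, concatenated in group order, feed stage 2.

The network is small enough that plain NumPy (im2col + BLAS matmul, with
hand-written backpropagation and Adam) trains it in seconds to minutes on one
CPU at the volume counts this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import SliceGroupSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractorConfig",
    "TrainedExtractor",
    "FeatureMatrix",
    "build_extractor",
    "train_extractor",
    "extract_features",
    "save_extractor",
    "load_extractor",
    "save_features",
    "load_features",
]


class ValidationError(ValueError):
    pass


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class ExtractorConfig:
    channels_per_group: int = 23
    n_groups: int = 4
    conv_widths: tuple[int, ...] = (16, 32, 64)  # per-group filter counts
    feature_dim_per_group: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 17
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if min(
            self.channels_per_group,
            self.n_groups,
            self.feature_dim_per_group,
            self.batch_size,
            *self.conv_widths,
        ) < 1:
            raise ValidationError("all extractor dimensions must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")

    @property
    def feature_dim(self) -> int:
        return self.feature_dim_per_group * self.n_groups


@dataclass
class FeatureMatrix:
    """n_studies x d concatenated per-group CNN features."""

    values: np.ndarray
    study_ids: list[str]
    block_spans: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.values.shape[1] != sum(hi - lo for lo, hi in self.block_spans):
            raise ValidationError("block spans do not cover the feature columns")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("features contain non-finite values")


# ---------------------------------------------------------------------------
# Layers


def _conv_forward(x_pad: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 valid conv of padded input with w (c_out, c_in, k, k).

    Returns (output (N, c_out, H, W), im2col matrix (N*H*W, c_in*k*k)).
    """
    c_out, c_in, k, _ = w.shape
    win = sliding_window_view(x_pad, (k, k), axis=(2, 3))  # (N, c_in, H, W, k, k)
    n, _, h, wd = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c_in * k * k)
    out = cols @ w.reshape(c_out, -1).T
    return out.reshape(n, h, wd, c_out).transpose(0, 3, 1, 2), cols


class GroupedConv2d:
    """Grouped convolution: channels split into n_groups independent blocks."""

    def __init__(self, n_groups, c_in, c_out, kernel, pad, rng, dtype):
        if c_in % n_groups or c_out % n_groups:
            raise ValidationError(
                f"channels ({c_in} -> {c_out}) must be divisible by {n_groups} groups"
            )
        self.g, self.k, self.pad = n_groups, kernel, pad
        self.cig, self.cog = c_in // n_groups, c_out // n_groups
        std = np.sqrt(2.0 / (self.cig * kernel * kernel))
        self.w = (rng.normal(0.0, std, size=(n_groups, self.cog, self.cig, kernel, kernel))
                  .astype(dtype))
        self.b = np.zeros((n_groups, self.cog), dtype=dtype)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        outs, cols = [], []
        for g in range(self.g):
            xg = xp[:, g * self.cig : (g + 1) * self.cig]
            o, c = _conv_forward(xg, self.w[g])
            outs.append(o + self.b[g][None, :, None, None])
            cols.append(c if train else None)
        self._cols = cols
        self._in_hw = x.shape[2:]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        h, wd = dout.shape[2:]
        dw = np.empty_like(self.w)
        db = np.empty_like(self.b)
        dxs = []
        q = self.k - 1 - self.pad
        for g in range(self.g):
            dg = dout[:, g * self.cog : (g + 1) * self.cog]
            d_flat = dg.transpose(0, 2, 3, 1).reshape(-1, self.cog)
            dw[g] = (d_flat.T @ self._cols[g]).reshape(self.cog, self.cig, self.k, self.k)
            db[g] = dg.sum(axis=(0, 2, 3))
            # dx = full conv of dout with spatially flipped, in/out-swapped kernels
            wt = self.w[g][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dgp = np.pad(dg, ((0, 0), (0, 0), (q, q), (q, q))) if q else dg
            dx_g, _ = _conv_forward(np.ascontiguousarray(dgp), np.ascontiguousarray(wt))
            dxs.append(dx_g)
        self.grads = [dw, db]
        self._cols = None
        return np.concatenate(dxs, axis=1)


class BatchNorm2d:
    def __init__(self, c, dtype, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.params = [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mean).astype(
                x.dtype
            )
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(
                x.dtype
            )
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std) if train else None
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        self.grads = [dgamma, dbeta]
        self._cache = None
        return dx


class ReLU:
    params: list = []

    def forward(self, x, train):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, dout):
        self.grads = []
        return dout * self._mask


class MaxPool2d:
    """2x2 max pooling, stride 2; ties broken toward the first position."""

    params: list = []

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValidationError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        self.grads = []
        return dx


class GlobalAvgPool:
    params: list = []

    def forward(self, x, train):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        h, w = self._hw
        self.grads = []
        return np.broadcast_to(dout[:, :, None, None] / (h * w), dout.shape + (h, w)).copy()


class Linear:
    def __init__(self, d_in, d_out, rng, dtype):
        self.w = (rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads = [self._x.T @ dout, dout.sum(axis=0)]
        self._x = None
        return dout @ self.w.T


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits; y holds class indices."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-30)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (_, p) in enumerate(layer.params):
                g = layer.grads[pi]
                self.m[li][pi] = self.b1 * self.m[li][pi] + (1 - self.b1) * g
                self.v[li][pi] = self.b2 * self.v[li][pi] + (1 - self.b2) * g * g
                p -= self.lr * (self.m[li][pi] / bc1) / (np.sqrt(self.v[li][pi] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Extractor


@dataclass
class TrainedExtractor:
    layers: list
    head: Linear | None
    config: ExtractorConfig
    train_log: list[float] = field(default_factory=list)
    trained: bool = False

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def all_layers(self) -> list:
        return self.layers + ([self.head] if self.head is not None else [])


def build_extractor(cfg: ExtractorConfig, n_classes: int = 3) -> TrainedExtractor:
    """Untrained extractor; parameter initialisation is seeded by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    dt = np.dtype(cfg.dtype)
    g = cfg.n_groups
    layers: list = []
    c_in = g * cfg.channels_per_group
    for width in cfg.conv_widths:
        c_out = g * width
        layers += [
            GroupedConv2d(g, c_in, c_out, 3, 1, rng, dt),
            BatchNorm2d(c_out, dt),
            ReLU(),
            MaxPool2d(),
        ]
        c_in = c_out
    layers += [
        GroupedConv2d(g, c_in, g * cfg.feature_dim_per_group, 1, 0, rng, dt),
        GlobalAvgPool(),
    ]
    head = Linear(cfg.feature_dim, n_classes, rng, dt)
    return TrainedExtractor(layers=layers, head=head, config=cfg)


def _to_batch(data: list[SliceGroupSet], cfg: ExtractorConfig, dtype) -> np.ndarray:
    """Stack SliceGroupSets to (N, n_groups*channels_per_group, H, W)."""
    out = []
    for gs in data:
        arr = gs.as_array()  # (G, S, H, W)
        if arr.shape[0] != cfg.n_groups or arr.shape[1] != cfg.channels_per_group:
            raise ValidationError(
                f"expected {cfg.n_groups} groups x {cfg.channels_per_group} slices, "
                f"got {arr.shape[0]} x {arr.shape[1]}"
            )
        out.append(arr.reshape(-1, *arr.shape[2:]))
    return np.asarray(np.stack(out), dtype=dtype)


def train_extractor(
    e: TrainedExtractor,
    data: list[SliceGroupSet],
    labels: list,
    cfg: ExtractorConfig | None = None,
) -> TrainedExtractor:
    """Minimise softmax cross-entropy of the temporary head with Adam.

    The head is discarded from the returned extractor; ``train_log`` holds the
    per-epoch mean loss. Deterministic for fixed seed and data order.
    """
    cfg = cfg or e.config
    if not data:
        raise ValidationError("training data is empty")
    if len(data) != len(labels):
        raise ValidationError("labels must align with data")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("training requires at least two classes")
    if cfg.epochs == 0:
        return e
    if e.head is None:
        raise ValidationError("extractor head already discarded; rebuild to retrain")
    if e.head.b.shape[0] != len(classes):
        # rebuild the temporary head to match the class count, same seed stream
        e.head = Linear(
            cfg.feature_dim, len(classes), np.random.default_rng(cfg.seed + 1), np.dtype(cfg.dtype)
        )
    dt = np.dtype(cfg.dtype)
    x_all = _to_batch(data, cfg, dt)
    y_all = np.array([classes.index(l) for l in labels])
    rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(e.all_layers(), cfg.learning_rate)
    n = len(data)
    log: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            feats = e.forward_features(x_all[idx], train=True)
            logits = e.head.forward(feats, train=True)
            loss, dlogits = softmax_xent(logits, y_all[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
            grad = e.head.backward(dlogits.astype(dt))
            for layer in reversed(e.layers):
                grad = layer.backward(grad)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
        logger.debug("epoch %d: mean loss %.4f", epoch, log[-1])
    return TrainedExtractor(
        layers=e.layers, head=None, config=cfg, train_log=log, trained=True
    )


def extract_features(
    e: TrainedExtractor, data: list[SliceGroupSet], study_ids: list[str] | None = None,
    allow_untrained: bool = False,
) -> FeatureMatrix:
    """Concatenated per-group pooled features, ordered by group index."""
    if not e.trained and not allow_untrained:
        raise ValidationError("extractor is untrained; pass allow_untrained=True to override")
    cfg = e.config
    dt = np.dtype(cfg.dtype)
    chunks = []
    bs = max(cfg.batch_size, 1)
    for start in range(0, len(data), bs):
        x = _to_batch(data[start : start + bs], cfg, dt)
        chunks.append(e.forward_features(x, train=False))
    values = np.vstack(chunks).astype(np.float64)
    f = cfg.feature_dim_per_group
    spans = [(g * f, (g + 1) * f) for g in range(cfg.n_groups)]
    ids = study_ids if study_ids is not None else [str(i) for i in range(len(data))]
    return FeatureMatrix(values=values, study_ids=list(ids), block_spans=spans)


# ---------------------------------------------------------------------------
# Persistence (single HDF5 checkpoint; track_times off for determinism)


def save_extractor(e: TrainedExtractor, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = e.config
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["trained"] = e.trained
        fh.attrs["train_log"] = np.asarray(e.train_log, dtype=np.float64)
        for k, v in vars(cfg).items():
            fh.attrs[f"cfg_{k}"] = v if not isinstance(v, tuple) else list(v)
        for i, layer in enumerate(e.layers):
            grp = fh.create_group(f"layer_{i}")
            grp.attrs["kind"] = type(layer).__name__
            for name, p in getattr(layer, "params", []):
                grp.create_dataset(name, data=p, track_times=False)
            if isinstance(layer, BatchNorm2d):
                grp.create_dataset("run_mean", data=layer.run_mean, track_times=False)
                grp.create_dataset("run_var", data=layer.run_var, track_times=False)
    return path


def load_extractor(path: str | Path) -> TrainedExtractor:
    with h5py.File(path, "r") as fh:
        kw = {}
        for k, v in fh.attrs.items():
            if k.startswith("cfg_"):
                kw[k[4:]] = v
        kw["conv_widths"] = tuple(int(x) for x in kw["conv_widths"])
        for key in ("channels_per_group", "n_groups", "feature_dim_per_group",
                    "epochs", "batch_size", "seed"):
            kw[key] = int(kw[key])
        kw["learning_rate"] = float(kw["learning_rate"])
        kw["dtype"] = str(kw["dtype"])
        cfg = ExtractorConfig(**kw)
        e = build_extractor(cfg)
        for i, layer in enumerate(e.layers):
            grp = fh[f"layer_{i}"]
            for name, p in getattr(layer, "params", []):
                p[...] = grp[name][()]
            if isinstance(layer, BatchNorm2d):
                layer.run_mean = grp["run_mean"][()]
                layer.run_var = grp["run_var"][()]
        e.trained = bool(fh.attrs["trained"])
        e.train_log = [float(x) for x in fh.attrs["train_log"]]
        if e.trained:
            e.head = None
    return e


def save_features(F: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as fh:
        fh.create_dataset("values", data=F.values, track_times=False)
        fh.attrs["study_ids"] = F.study_ids
        fh.attrs["block_spans"] = np.asarray(F.block_spans, dtype=np.int64)
    return path


def load_features(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as fh:
        return FeatureMatrix(
            values=fh["values"][()],
            study_ids=[str(s) for s in fh.attrs["study_ids"]],
            block_spans=[tuple(int(x) for x in row) for row in fh.attrs["block_spans"]],
        )
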