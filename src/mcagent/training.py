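"""Seeded embedding training for any of the package's objectives.

The optimization protocol mirrors standard practice for hypersphere
metric learning: an adaptive-moment (Adam) optimizer at initial learning
rate 1e-3 with an exponential per-epoch decay of 0.95, features L2
normalized before every loss call, and class centers re-normalized to
unit length at every loss evaluation.  The backbone is pluggable; at desk
scale a small dense network (default: a single linear map) suffices for
vector inputs and a small convolutional head for images, and both are
trained jointly with the center bank through the package's reverse-mode
autodiff core.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.vq import kmeans2

from . import autodiff as ad
from .autodiff import Tensor, matmul, tanh, value_of
from .core_geometry import CenterBank, FeatureBatch, normalize_rows
from .mca_losses import (
    ArcFaceConfig,
    LossBreakdown,
    MCAConfig,
    SoftTripleConfig,
    TripletConfig,
    arcface_loss,
    mca_loss,
    softtriple_loss,
    triplet_hard_mining_loss,
)

__all__ = [
    "TrainConfig",
    "EmbedderModel",
    "build_backbone",
    "train_embedder",
    "embed",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters.

    ``embed_dim`` defaults to 384, the feature dimension used with a
    full-scale convolutional backbone; desk-scale experiments override it
    downward.  ``lr_decay`` is the per-epoch exponential factor.
    """

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_decay: float = 0.95
    embed_dim: int = 384
    backbone: str = "dense"
    hidden_dim: int = 0          # dense backbone: 0 = pure linear map
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")


class Backbone:
    """Parametric map from raw inputs to (unnormalized) embeddings."""

    kind = "base"

    def __init__(self):
        self.params: list[Tensor] = []

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        for p, a in zip(self.params, arrays):
            p.value[...] = a


class DenseBackbone(Backbone):
    """Linear map, optionally with one tanh hidden layer."""

    kind = "dense"

    def __init__(self, input_dim: int, embed_dim: int, hidden_dim: int = 0, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_dim, self.embed_dim, self.hidden_dim = input_dim, embed_dim, hidden_dim
        dims = [input_dim] + ([hidden_dim] if hidden_dim else []) + [embed_dim]
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = Tensor(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in), requires_grad=True)
            b = Tensor(np.zeros(fan_out), requires_grad=True)
            self.weights.append(w)
            self.biases.append(b)
            self.params.extend([w, b])

    def forward(self, x: np.ndarray):
        h = ad.as_tensor(np.asarray(x, dtype=np.float64))
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = matmul(h, w) + b
            if i < len(self.weights) - 1:
                h = tanh(h)
        return h


class SmallConvBackbone(Backbone):
    """One 3x3 stride-2 convolution + tanh + spatial mean pool + linear head.

    Implemented by patch extraction (im2col) so the whole forward pass is
    matrix products the autodiff core differentiates.
    """

    kind = "smallconv"

    def __init__(self, image_size: int, embed_dim: int, channels: int = 8, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.image_size, self.embed_dim, self.channels = image_size, embed_dim, channels
        self.kernel = Tensor(rng.standard_normal((9, channels)) / 3.0, requires_grad=True)
        self.kbias = Tensor(np.zeros(channels), requires_grad=True)
        self.head_w = Tensor(rng.standard_normal((channels, embed_dim)) / np.sqrt(channels), requires_grad=True)
        self.head_b = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.params = [self.kernel, self.kbias, self.head_w, self.head_b]
        # precompute im2col gather indices for stride-2 valid patches
        s = image_size
        rows = np.arange(0, s - 2, 2)
        self._out = len(rows)
        ii, jj = np.meshgrid(rows, rows, indexing="ij")
        di, dj = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        self._pi = (ii[:, :, None] + di.reshape(-1)[None, None, :]).reshape(-1)
        self._pj = (jj[:, :, None] + dj.reshape(-1)[None, None, :]).reshape(-1)

    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=np.float64)
        n = x.shape[0]
        patches = x[:, self._pi, self._pj].reshape(n * self._out * self._out, 9)
        h = tanh(matmul(ad.as_tensor(patches), self.kernel) + self.kbias)
        pooled = h.reshape((n, self._out * self._out, self.channels)).mean(axis=1)
        return matmul(pooled, self.head_w) + self.head_b


_EXTERNAL_BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, factory: Callable) -> None:
    """Register an external backbone factory: (input_shape, embed_dim, seed) -> Backbone."""
    _EXTERNAL_BACKBONES[name] = factory


def build_backbone(kind: str, input_shape, embed_dim: int, seed: int = 0, hidden_dim: int = 0) -> Backbone:
    """Construct a deterministic, seeded backbone of the requested kind."""
    if kind == "dense":
        input_dim = int(np.atleast_1d(input_shape)[-1])
        return DenseBackbone(input_dim, embed_dim, hidden_dim=hidden_dim, seed=seed)
    if kind == "smallconv":
        size = int(np.atleast_1d(input_shape)[-1])
        return SmallConvBackbone(size, embed_dim, seed=seed)
    if kind in _EXTERNAL_BACKBONES:
        bb = _EXTERNAL_BACKBONES[kind](input_shape, embed_dim, seed)
        probe = np.zeros((1,) + tuple(np.atleast_1d(input_shape)))
        out = value_of(bb.forward(probe))
        if out.shape != (1, embed_dim):
            raise ValueError(
                f"external backbone '{kind}' produced shape {out.shape}, "
                f"expected (1, {embed_dim})"
            )
        return bb
    raise ValueError(f"unknown backbone kind '{kind}'")


@dataclass
class EmbedderModel:
    """A trained (or freshly initialized) embedder with its center bank."""

    backbone: Backbone
    centers: Tensor                   # (num_train_classes, C, d), trainable
    class_ids: np.ndarray             # original identity of each center row
    train_cfg: TrainConfig
    loss_cfg: object
    history: list = field(default_factory=list)   # per-epoch LossBreakdown (floats)

    def embed(self, inputs) -> np.ndarray:
        return embed(self, inputs)

    def center_bank(self) -> CenterBank:
        w = self.centers.value
        return CenterBank(w / np.linalg.norm(w, axis=-1, keepdims=True))


class Adam:
    """Adaptive-moment estimation over a flat list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _loss_forward(feats_t, labels, centers_t, loss_cfg) -> LossBreakdown:
    """Dispatch on the loss config type; always returns a LossBreakdown."""
    if isinstance(loss_cfg, MCAConfig):
        Y, C, d = centers_t.shape
        w = normalize_rows(centers_t.reshape((Y * C, d))).reshape((Y, C, d))
        return mca_loss(feats_t, w, loss_cfg, labels=labels)
    if isinstance(loss_cfg, TripletConfig):
        total = triplet_hard_mining_loss(feats_t, loss_cfg.margin, labels=labels)
        zero = 0.0
        return LossBreakdown(total, zero, zero, total, 0.0, 1.0)
    Y, C, d = centers_t.shape
    w = normalize_rows(centers_t.reshape((Y * C, d))).reshape((Y, C, d))
    if isinstance(loss_cfg, ArcFaceConfig):
        total = arcface_loss(feats_t, w, loss_cfg.m, loss_cfg.r, labels=labels)
        return LossBreakdown(total, total, 0.0, 0.0, 0.0, 0.0)
    if isinstance(loss_cfg, SoftTripleConfig):
        total = softtriple_loss(feats_t, w, loss_cfg, labels=labels)
        return LossBreakdown(total, total, 0.0, 0.0, loss_cfg.tau, 0.0)
    raise TypeError(f"unsupported loss config {type(loss_cfg).__name__}")


def _centers_per_class(loss_cfg) -> int:
    if isinstance(loss_cfg, (MCAConfig, SoftTripleConfig)):
        return loss_cfg.centers_per_class
    return 1


def _class_aware_batches(labels, batch_size, rng):
    """Batches guaranteeing >= 2 classes and a positive pair per batch
    (needed by the sample-level triplet baseline): sample P classes x Q."""
    classes = np.unique(labels)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    q = max(2, batch_size // max(2, min(len(classes), batch_size // 2)))
    p = max(2, batch_size // q)
    order = rng.permutation(classes)
    batches = []
    for start in range(0, len(order), p):
        chosen = order[start : start + p]
        if len(chosen) < 2:
            chosen = order[-2:]
        idx = np.concatenate(
            [rng.choice(by_class[c], size=min(q, len(by_class[c])), replace=False) for c in chosen]
        )
        batches.append(idx)
    return batches


def train_embedder(dataset, train_cfg: TrainConfig, loss_cfg, train_indices=None) -> EmbedderModel:
    """Jointly optimize a backbone and center bank under the chosen loss.

    ``dataset`` is either a ``SyntheticDataset``-like object with
    ``vectors``/``labels`` (or ``images``/``labels``) attributes or an
    ``(X, y)`` tuple.  ``train_indices`` restricts training to a subset
    (used by the open-set protocol to withhold unseen identities).
    Labels are remapped to a dense 0..Y-1 range internally; the mapping is
    kept on the model.  Fully reproducible from the configs' seeds.
    """
    X, y = _unpack_dataset(dataset)
    if train_indices is not None:
        X, y = X[train_indices], y[train_indices]
    class_ids = np.unique(y)
    if class_ids.size < 2:
        raise ValueError("training requires at least 2 classes")
    dense = np.searchsorted(class_ids, y)

    rng = np.random.default_rng(train_cfg.seed)
    input_shape = X.shape[1:]
    backbone = build_backbone(train_cfg.backbone, input_shape, train_cfg.embed_dim,
                              seed=train_cfg.seed, hidden_dim=train_cfg.hidden_dim)
    C = _centers_per_class(loss_cfg)
    # warm-start each class's centers by k-means on its initial embeddings:
    # symmetric random starts risk a merged fixed point (uniform assignment,
    # centers stuck at the between-cluster bisector), and random sample picks
    # can leave a local cluster with no nearby center; k-means seeds one
    # center per empirical cluster, which joint training then refines
    w0 = rng.standard_normal((class_ids.size, C, train_cfg.embed_dim))
    init_feats = value_of(normalize_rows(value_of(backbone.forward(X))))
    for row, cid in enumerate(class_ids):
        idx = np.flatnonzero(y == cid)
        if idx.size >= C:
            km, _ = kmeans2(init_feats[idx], C, minit="++",
                            seed=int(rng.integers(2**31)))
            good = np.linalg.norm(km, axis=1) > 1e-9
            w0[row, good] = km[good] + 0.01 * w0[row, good]
    w0 /= np.linalg.norm(w0, axis=-1, keepdims=True)
    centers = Tensor(w0, requires_grad=True)

    model = EmbedderModel(backbone, centers, class_ids, train_cfg, loss_cfg)
    needs_class_batches = isinstance(loss_cfg, TripletConfig)
    opt = Adam(backbone.params + [centers], train_cfg.learning_rate)
    n = X.shape[0]
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.learning_rate * train_cfg.lr_decay**epoch
        if needs_class_batches:
            batches = _class_aware_batches(dense, train_cfg.batch_size, rng)
        else:
            perm = rng.permutation(n)
            batches = [perm[s : s + train_cfg.batch_size] for s in range(0, n, train_cfg.batch_size)]
        acc = np.zeros(4)
        for idx in batches:
            feats = normalize_rows(backbone.forward(X[idx]))
            bd = _loss_forward(feats, dense[idx], centers, loss_cfg)
            total = bd.total if ad.is_tensor(bd.total) else ad.as_tensor(bd.total)
            if not np.isfinite(value_of(total)):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, batch starting {idx[0]}")
            opt.zero_grad()
            total.backward()
            opt.step()
            d = bd.detached()
            acc += np.array([d.total, d.softmax_term, d.reg_term, d.triplet_term]) * len(idx)
        acc /= n if not needs_class_batches else sum(len(b) for b in batches)
        model.history.append(LossBreakdown(*acc, tau=getattr(loss_cfg, "tau", 0.0),
                                           beta=getattr(loss_cfg, "beta", 0.0)))
    return model


def _unpack_dataset(dataset):
    if isinstance(dataset, tuple):
        X, y = dataset
    elif hasattr(dataset, "vectors"):
        X, y = dataset.vectors, dataset.labels
    elif hasattr(dataset, "images"):
        X, y = dataset.images, dataset.labels
    else:
        raise TypeError("dataset must be (X, y) or expose vectors/images and labels")
    return np.asarray(X, dtype=np.float64), np.asarray(y, dtype=np.intp)


def embed(model: EmbedderModel, inputs) -> np.ndarray:
    """Map raw inputs to unit-norm embeddings (deterministic inference)."""
    out = value_of(model.backbone.forward(np.asarray(inputs, dtype=np.float64)))
    return np.asarray(value_of(normalize_rows(out)))


# --------------------------------------------------------------------------
# Checkpointing: a single zip archive of arrays + JSON configs
# --------------------------------------------------------------------------

def save_checkpoint(model: EmbedderModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"centers": model.centers.value, "class_ids": model.class_ids}
    for i, a in enumerate(model.backbone.state()):
        arrays[f"param_{i}"] = a
    meta = {
        "train_cfg": asdict(model.train_cfg),
        "loss_cfg": {"type": type(model.loss_cfg).__name__, **asdict(model.loss_cfg)},
        "backbone_kind": model.backbone.kind,
        "input_meta": _backbone_meta(model.backbone),
        "history": [
            [h.total, h.softmax_term, h.reg_term, h.triplet_term] for h in model.history
        ],
    }
    buf = BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1))


_LOSS_TYPES = {
    "MCAConfig": MCAConfig,
    "TripletConfig": TripletConfig,
    "ArcFaceConfig": ArcFaceConfig,
    "SoftTripleConfig": SoftTripleConfig,
}


def _backbone_meta(bb: Backbone) -> dict:
    if isinstance(bb, DenseBackbone):
        return {"input_dim": bb.input_dim, "hidden_dim": bb.hidden_dim}
    if isinstance(bb, SmallConvBackbone):
        return {"image_size": bb.image_size, "channels": bb.channels}
    return {}


def load_checkpoint(path) -> EmbedderModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(BytesIO(zf.read("arrays.npz")))
        train_cfg = TrainConfig(**meta["train_cfg"])
        loss_meta = dict(meta["loss_cfg"])
        loss_cls = _LOSS_TYPES[loss_meta.pop("type")]
        loss_cfg = loss_cls(**loss_meta)
        kind, bmeta = meta["backbone_kind"], meta["input_meta"]
        if kind == "dense":
            bb = DenseBackbone(bmeta["input_dim"], train_cfg.embed_dim,
                               bmeta["hidden_dim"], seed=train_cfg.seed)
        elif kind == "smallconv":
            bb = SmallConvBackbone(bmeta["image_size"], train_cfg.embed_dim,
                                   bmeta["channels"], seed=train_cfg.seed)
        else:
            raise ValueError(f"cannot restore external backbone '{kind}'")
        bb.load_state([arrays[f"param_{i}"] for i in range(len(bb.params))])
        model = EmbedderModel(
            bb,
            Tensor(arrays["centers"], requires_grad=True),
            arrays["class_ids"],
            train_cfg,
            loss_cfg,
            history=[LossBreakdown(*row, tau=getattr(loss_cfg, "tau", 0.0),
                                   beta=getattr(loss_cfg, "beta", 0.0))
                     for row in meta["history"]],
        )
        return model
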