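"""Open-set identification protocol: identity-disjoint folds, gallery/query
splits and k-NN classification.

Identities are split 50/50 into *seen* (used to train the embedder) and
*unseen* (withheld); evaluation happens only on the unseen identities,
whose samples are split 7:3 per identity into an enrolled gallery and
held-out queries.  Queries are classified by a majority vote among their
k = 5 nearest gallery embeddings (Euclidean distance — equivalent to
cosine ordering on unit vectors).  Two-fold cross-validation swaps the
seen and unseen halves; accuracy is reported as average over folds with
the per-fold minimum and maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .mca_losses import MCAConfig
from .training import EmbedderModel, TrainConfig, embed, train_embedder

__all__ = [
    "OpenSetSplit",
    "EvalReport",
    "make_openset_split",
    "knn_classify",
    "evaluate_fold",
    "twofold_cross_validate",
    "center_count_sweep",
]


class ProtocolError(ValueError):
    """Raised when the open-set protocol is violated (leakage, bad split)."""


@dataclass
class OpenSetSplit:
    """One fold of the identity-disjoint open-set partition."""

    fold: int
    seen: np.ndarray                  # identities used for representation learning
    unseen: np.ndarray                # withheld evaluation identities
    gallery_idx: np.ndarray           # sample indices (into the full dataset)
    query_idx: np.ndarray

    def train_indices(self, labels: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.isin(labels, self.seen))


@dataclass
class EvalReport:
    """Accuracy aggregated over folds, in the 'average:[min, max]' style."""

    per_fold: list
    k: int
    config: dict = field(default_factory=dict)

    @property
    def average(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def minimum(self) -> float:
        return float(np.min(self.per_fold))

    @property
    def maximum(self) -> float:
        return float(np.max(self.per_fold))

    def __str__(self) -> str:
        return f"Average Accuracy (%):[Minimum, Maximum] = {self.average:.2f}:[{self.minimum:.2f}, {self.maximum:.2f}]"


def make_openset_split(
    labels,
    fraction_unseen: float = 0.5,
    fold: int = 0,
    seed: int = 0,
    gallery_fraction: float = 0.7,
) -> OpenSetSplit:
    """Identity-disjoint seen/unseen partition plus per-identity 7:3
    gallery/query sample split on the unseen (evaluation) identities.

    Identities are shuffled once from the seed; fold 0 takes the first
    half as unseen, fold 1 the complement, so the two folds are exact
    complements of each other.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ProtocolError("need at least 2 identities")
    if not (0 < fraction_unseen < 1):
        raise ProtocolError("fraction_unseen must be in (0, 1)")
    if fold not in (0, 1):
        raise ProtocolError("fold must be 0 or 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)
    n_unseen = int(round(fraction_unseen * ids.size))
    first, second = order[:n_unseen], order[n_unseen:]
    unseen, seen = (first, second) if fold == 0 else (second, first)

    gallery, query = [], []
    for ident in np.sort(unseen):
        idx = np.flatnonzero(labels == ident)
        if idx.size < 2:
            raise ProtocolError(
                f"identity {ident!r} has {idx.size} sample(s); need >= 2 "
                "to form both gallery and query"
            )
        sub = np.random.default_rng((seed, int(fold), int(ident)))
        perm = sub.permutation(idx)
        n_gal = int(np.ceil(gallery_fraction * idx.size))
        n_gal = min(n_gal, idx.size - 1)  # keep at least one query sample
        gallery.append(perm[:n_gal])
        query.append(perm[n_gal:])
    return OpenSetSplit(
        fold=fold,
        seen=np.sort(seen),
        unseen=np.sort(unseen),
        gallery_idx=np.concatenate(gallery),
        query_idx=np.concatenate(query),
    )


def knn_classify(gallery_vectors, gallery_labels, query_vectors, k: int = 5) -> np.ndarray:
    """Majority vote among the k nearest gallery points.

    Ties between labels are broken by the smaller summed distance of the
    tied labels' votes, then by the smaller label value.
    """
    gallery_vectors = np.asarray(gallery_vectors, dtype=float)
    query_vectors = np.asarray(query_vectors, dtype=float)
    gallery_labels = np.asarray(gallery_labels)
    if gallery_vectors.shape[0] == 0:
        raise ProtocolError("gallery is empty")
    if k < 1:
        raise ProtocolError("k must be >= 1")
    if k > gallery_vectors.shape[0]:
        warnings.warn(f"k={k} clamped to gallery size {gallery_vectors.shape[0]}", stacklevel=2)
        k = gallery_vectors.shape[0]
    dists = cdist(query_vectors, gallery_vectors)
    # stable argsort so equal distances resolve deterministically
    nearest = np.argsort(dists, axis=1, kind="stable")[:, :k]
    preds = np.empty(query_vectors.shape[0], dtype=gallery_labels.dtype)
    for i, nb in enumerate(nearest):
        votes = gallery_labels[nb]
        d = dists[i, nb]
        cand, counts = np.unique(votes, return_counts=True)
        best = counts == counts.max()
        cand = cand[best]
        if cand.size > 1:
            sums = np.array([d[votes == c].sum() for c in cand])
            cand = cand[sums == sums.min()]
        preds[i] = cand.min()
    return preds


def evaluate_fold(model: EmbedderModel, dataset, split: OpenSetSplit, k: int = 5) -> float:
    """Open-set accuracy (%) of ``model`` on the fold's unseen identities."""
    X, y = _dataset_arrays(dataset)
    if np.intersect1d(model.class_ids, split.unseen).size:
        raise ProtocolError(
            "leakage: the model was trained on identities that appear in "
            "this fold's unseen evaluation set"
        )
    gal = embed(model, X[split.gallery_idx])
    qry = embed(model, X[split.query_idx])
    preds = knn_classify(gal, y[split.gallery_idx], qry, k=k)
    return 100.0 * float(np.mean(preds == y[split.query_idx]))


def _dataset_arrays(dataset):
    if isinstance(dataset, tuple):
        X, y = dataset
    elif hasattr(dataset, "vectors"):
        X, y = dataset.vectors, dataset.labels
    else:
        X, y = dataset.images, dataset.labels
    return np.asarray(X, dtype=float), np.asarray(y)


def twofold_cross_validate(
    dataset,
    train_cfg: TrainConfig,
    loss_cfg,
    k: int = 5,
    seed: int = 0,
    fraction_unseen: float = 0.5,
) -> EvalReport:
    """Train one model per fold on the seen identities, evaluate on the
    unseen ones, and aggregate average/min/max accuracy."""
    X, y = _dataset_arrays(dataset)
    accs = []
    for fold in (0, 1):
        split = make_openset_split(y, fraction_unseen, fold, seed)
        model = train_embedder((X, y), train_cfg, loss_cfg,
                               train_indices=split.train_indices(y))
        accs.append(evaluate_fold(model, (X, y), split, k=k))
    return EvalReport(
        per_fold=accs,
        k=k,
        config={
            "loss": type(loss_cfg).__name__,
            "loss_cfg": vars(loss_cfg) if hasattr(loss_cfg, "__dict__") else repr(loss_cfg),
            "seed": seed,
            "fraction_unseen": fraction_unseen,
        },
    )


def center_count_sweep(
    dataset,
    train_cfg: TrainConfig,
    loss_cfg: MCAConfig,
    c_values: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> list:
    """Repeat the two-fold cross-validation for each center count C.

    Returns a list of rows ``{"C": c, "average": ..., "minimum": ...,
    "maximum": ...}`` suitable for tabulation or plotting.
    """
    if not len(c_values):
        raise ValueError("c_values must be nonempty")
    rows = []
    for c in c_values:
        rep = twofold_cross_validate(dataset, train_cfg, loss_cfg.with_(centers_per_class=int(c)),
                                     k=k, seed=seed)
        rows.append({"C": int(c), "average": rep.average,
                     "minimum": rep.minimum, "maximum": rep.maximum})
    return rows
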