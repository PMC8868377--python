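"""Embedding-space primitives for multi-center agent learning.

Features live on the unit hypersphere.  Each class ``j`` owns ``C``
trainable unit-norm centers ``W_j^c``; a sample's *agent* for class ``j``
is the convex combination of that class's centers under an
entropy-regularized assignment distribution

    p[i, j, c] = softmax_c( f_i · W_j^c / gamma ),

the closed-form solution of the smoothed max-similarity program.  As the
temperature ``gamma`` goes to zero the agent logit recovers the hard
max-center similarity; as it grows the assignment tends to uniform.

All functions accept plain ``ndarray`` inputs or autodiff ``Tensor``
inputs and return the matching kind, so the same code path serves both
evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import exp, sqrt, tmax, tsum, value_of

__all__ = [
    "DegenerateInputError",
    "FeatureBatch",
    "CenterBank",
    "normalize_rows",
    "center_similarities",
    "assignment_distribution",
    "compute_agents",
    "agent_logits",
    "max_center_similarity",
]


class DegenerateInputError(ValueError):
    """Raised for inputs the geometry cannot handle (e.g. zero-norm rows)."""


def normalize_rows(matrix):
    """Scale every row of ``matrix`` to unit L2 norm.

    Direction is preserved; a zero-norm row is rejected with the offending
    row index, since it has no direction.
    """
    vals = value_of(matrix)
    norms = np.linalg.norm(vals, axis=-1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise DegenerateInputError(f"zero-norm row at index {int(bad[0])}")
    return matrix / sqrt(tsum(matrix * matrix, axis=-1, keepdims=True))


@dataclass
class FeatureBatch:
    """Unit-norm embedding vectors paired with integer class labels."""

    vectors: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if value_of(self.vectors).ndim != 2:
            raise ValueError("vectors must be a 2-D (n, d) array")
        if self.labels.shape != (value_of(self.vectors).shape[0],):
            raise ValueError("labels must be 1-D with one entry per row of vectors")

    @classmethod
    def from_raw(cls, vectors, labels) -> "FeatureBatch":
        """Normalize raw vectors onto the hypersphere and wrap them."""
        return cls(normalize_rows(vectors), labels)

    @property
    def n(self) -> int:
        return value_of(self.vectors).shape[0]

    @property
    def dim(self) -> int:
        return value_of(self.vectors).shape[1]


@dataclass
class CenterBank:
    """Trainable class centers: a (num_classes, centers_per_class, dim) array.

    Centers are re-normalized to unit length on every read for loss
    computation (see :meth:`normalized`), so the unit-norm invariant holds
    under any optimizer update rule.
    """

    weights: np.ndarray
    num_classes: int = field(default=0)
    centers_per_class: int = field(default=0)
    embed_dim: int = field(default=0)

    def __post_init__(self):
        shape = value_of(self.weights).shape
        if len(shape) != 3:
            raise ValueError("weights must have shape (Y, C, d)")
        self.num_classes, self.centers_per_class, self.embed_dim = shape
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.centers_per_class < 1 or self.embed_dim < 2:
            raise ValueError("need C >= 1 and d >= 2")

    @classmethod
    def random(cls, num_classes: int, centers_per_class: int, embed_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((num_classes, centers_per_class, embed_dim))
        return cls(w / np.linalg.norm(w, axis=-1, keepdims=True))

    def normalized(self):
        """Unit-norm view of the centers (flattens then renormalizes rows)."""
        Y, C, d = self.num_classes, self.centers_per_class, self.embed_dim
        flat = self.weights.reshape((Y * C, d)) if hasattr(self.weights, "reshape") else None
        return normalize_rows(flat).reshape((Y, C, d))


def _bank_weights(bank):
    """Unit-norm (Y, C, d) weights from a CenterBank or a raw array."""
    if isinstance(bank, CenterBank):
        return bank.normalized()
    return bank


def center_similarities(feats, bank):
    """Cosine similarities: entry (i, j, c) = f_i · W_j^c, shape (n, Y, C)."""
    f = feats.vectors if isinstance(feats, FeatureBatch) else feats
    w = _bank_weights(bank)
    if value_of(f).shape[-1] != value_of(w).shape[-1]:
        raise ValueError(
            f"embedding dim mismatch: features d={value_of(f).shape[-1]}, "
            f"centers d={value_of(w).shape[-1]}"
        )
    n, d = value_of(f).shape
    Y, C, _ = value_of(w).shape
    fr = f.reshape((n, 1, 1, d)) if hasattr(f, "reshape") else f
    wr = w.reshape((1, Y, C, d))
    return tsum(fr * wr, axis=-1)


def assignment_distribution(sims, gamma: float):
    """Closed-form softmax assignment of each sample over a class's centers.

    ``p[i, j, c] = exp(s_ijc / gamma) / sum_c' exp(s_ijc' / gamma)``,
    computed with a max shift for overflow safety and differentiable in the
    similarities.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    shift = np.max(value_of(sims), axis=-1, keepdims=True)  # constant shift
    z = exp((sims - shift) * (1.0 / gamma))
    return z / tsum(z, axis=-1, keepdims=True)


def compute_agents(p, bank):
    """Agents A[i, j] = sum_c p[i, j, c] * W_j^c, shape (n, Y, d).

    Gradients flow through both the assignment ``p`` and the centers.
    """
    w = _bank_weights(bank)
    n, Y, C = value_of(p).shape
    Yw, Cw, d = value_of(w).shape
    if (Y, C) != (Yw, Cw):
        raise ValueError(f"assignment shape {(Y, C)} does not match bank {(Yw, Cw)}")
    pr = p.reshape((n, Y, C, 1))
    wr = w.reshape((1, Y, C, d))
    return tsum(pr * wr, axis=2)


def agent_logits(feats, agents):
    """Cosine logits against every class agent: entry (i, j) = f_i · A[i, j]."""
    f = feats.vectors if isinstance(feats, FeatureBatch) else feats
    n, d = value_of(f).shape
    na, Y, da = value_of(agents).shape
    if (n, d) != (na, da):
        raise ValueError(f"feature shape {(n, d)} does not match agents {(na, da)}")
    fr = f.reshape((n, 1, d))
    return tsum(fr * agents, axis=-1)


def max_center_similarity(feats, bank):
    """Hard max-center similarity, entry (i, j) = max_c f_i · W_j^c.

    The zero-temperature limit of the agent logit.
    """
    return tmax(center_similarities(feats, bank), axis=-1)
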