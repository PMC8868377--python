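"""Loss functions for multi-center agent metric learning.

The joint objective is

    L = L_softmax_agent + tau * R(centers) + beta * L_triplet_KNA

where

* ``L_softmax_agent`` is a scaled cross-entropy over cosine logits
  ``lam * f_i . A_{i,j}`` against per-class agents (convex combinations of
  each class's centers under the entropy-regularized assignment);
* ``R`` is an L2,1-norm diversity penalty on pairwise center differences
  within each class, normalized by ``Y * C * (C - 1)``;
* ``L_triplet_KNA`` is a hinge over the K negative-class agents nearest to
  the anchor feature — an implicit hard-negative mining over proxies:
  ``sum_k max(0, f.A_k - f.A_y + margin)``.

Config special cases reproduce the ablation family purely by
configuration: ``C=1, beta=0`` is single-center normalized SoftMax;
``C>1, beta=0`` is multi-center SoftMax; ``beta>0`` adds the agent
triplet.  Baselines used for comparison (sample-level batch-hard triplet,
additive-angular-margin softmax, SoftTriple) live here too so every
objective trains through the same machinery.

All losses take either plain arrays or autodiff Tensors for the features
and center weights; with Tensors the returned terms are Tensors and
support ``backward()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import arccos, clip, cos, exp, log, maximum, sqrt, tmax, tmean, tsum, value_of
from .core_geometry import (
    CenterBank,
    FeatureBatch,
    agent_logits,
    assignment_distribution,
    center_similarities,
    compute_agents,
)

__all__ = [
    "MCAConfig",
    "TripletConfig",
    "ArcFaceConfig",
    "SoftTripleConfig",
    "LossBreakdown",
    "MarginAuditReport",
    "center_diversity_reg",
    "softmax_agent_loss",
    "knn_negative_agents",
    "knnat_loss",
    "mca_loss",
    "margin_audit",
    "triplet_hard_mining_loss",
    "arcface_loss",
    "softtriple_loss",
]

# keeps sqrt differentiable when a pairwise difference is exactly zero;
# perturbs the regularizer value by at most 1e-12 per pair
_SQRT_EPS = 1e-24


@dataclass(frozen=True)
class MCAConfig:
    """Hyperparameters of the multi-center agent loss.

    Defaults are the operating point reported for the 100-identity
    multi-view cattle benchmark: logit scale ``lam=24``, regularizer weight
    ``tau=0.2``, assignment temperature ``gamma=0.1``, ``C=10`` centers per
    class, triplet margin 0.4 over the ``K=2`` nearest negative agents with
    weight ``beta=0.1``.
    """

    lam: float = 24.0
    gamma: float = 0.1
    tau: float = 0.2
    centers_per_class: int = 10
    k_neg: int = 2
    margin: float = 0.4
    beta: float = 0.1
    renormalize_agents: bool = False  # off by default: hinge uses raw agent inner products

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.tau < 0 or self.beta < 0 or self.margin < 0:
            raise ValueError("tau, beta and margin must be nonnegative")
        if self.centers_per_class < 1 or self.k_neg < 1:
            raise ValueError("centers_per_class and k_neg must be >= 1")

    def with_(self, **kw) -> "MCAConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TripletConfig:
    """Sample-level batch-hard triplet baseline (margin 0.5)."""

    margin: float = 0.5


@dataclass(frozen=True)
class ArcFaceConfig:
    """Additive angular margin baseline (m=0.1, r=32, single center)."""

    m: float = 0.1
    r: float = 32.0


@dataclass(frozen=True)
class SoftTripleConfig:
    """SoftTriple baseline (lam=24, gamma=0.05, tau=0.2, margin=0.01)."""

    lam: float = 24.0
    gamma: float = 0.05
    tau: float = 0.2
    centers_per_class: int = 10
    margin: float = 0.01


@dataclass
class LossBreakdown:
    """Additive decomposition: total = softmax + tau*reg + beta*triplet."""

    total: object
    softmax_term: object
    reg_term: object
    triplet_term: object
    tau: float = 0.0
    beta: float = 0.0

    def detached(self) -> "LossBreakdown":
        return LossBreakdown(
            float(value_of(self.total)),
            float(value_of(self.softmax_term)),
            float(value_of(self.reg_term)),
            float(value_of(self.triplet_term)),
            self.tau,
            self.beta,
        )


def _as_feats_labels(feats, labels=None):
    if isinstance(feats, FeatureBatch):
        return feats.vectors, feats.labels
    if labels is None:
        raise ValueError("labels are required when features are a raw array")
    return feats, np.asarray(labels, dtype=np.intp)


def _pair_norm_sum(w):
    """Sum over classes of all ordered-pair center distances ||W_j^s - W_j^t||."""
    Y, C, d = value_of(w).shape
    s_idx, t_idx = np.nonzero(~np.eye(C, dtype=bool))
    diffs = w[:, s_idx, :] - w[:, t_idx, :]
    return tsum(sqrt(tsum(diffs * diffs, axis=-1) + _SQRT_EPS))


def center_diversity_reg(bank):
    """L2,1-norm center-diversity regularizer.

    ``sum_j sum_t ||S_j^t||_{2,1} / (Y*C*(C-1))`` where the columns of
    ``S_j^t`` are the differences ``W_j^s - W_j^t``; zero when ``C = 1``
    (no pairs) or when all same-class centers coincide.
    """
    w = bank.normalized() if isinstance(bank, CenterBank) else bank
    Y, C, d = value_of(w).shape
    if C == 1:
        return 0.0 if not ad.is_tensor(w) else ad.Tensor(0.0, parents=(w,), backward=lambda g: (np.zeros((Y, C, d)),))
    return _pair_norm_sum(w) / float(Y * C * (C - 1))


def _agent_state(feats, labels, bank, gamma):
    """Shared forward pass: similarities -> assignment -> agents -> logits."""
    f, y = _as_feats_labels(feats, labels)
    sims = center_similarities(f, bank)
    p = assignment_distribution(sims, gamma)
    agents = compute_agents(p, bank)
    logits = agent_logits(f, agents)
    return f, y, agents, logits


def _cross_entropy(scaled_logits, labels):
    """Row-wise -log softmax at the label, stable under a max shift."""
    shift = np.max(value_of(scaled_logits), axis=1, keepdims=True)
    z = scaled_logits - shift
    lse = log(tsum(exp(z), axis=1))
    n = value_of(scaled_logits).shape[0]
    picked = z[np.arange(n), labels]
    return lse - picked


def softmax_agent_loss(feats, bank, cfg: MCAConfig, labels=None, per_sample: bool = False):
    """SoftMax over multi-center agent logits plus the diversity regularizer.

    Returns ``(softmax_term, reg_term)``; the softmax term is the batch
    mean of the per-sample cross-entropies unless ``per_sample`` is set.
    """
    f, y, _, logits = _agent_state(feats, labels, bank, cfg.gamma)
    ce = _cross_entropy(logits * cfg.lam, y)
    if not np.all(np.isfinite(value_of(ce))):
        bad = int(np.flatnonzero(~np.isfinite(value_of(ce)))[0])
        raise FloatingPointError(f"non-finite loss at batch index {bad}")
    reg = center_diversity_reg(bank)
    return (ce if per_sample else tmean(ce)), reg


def knn_negative_agents(logits, labels, k: int) -> np.ndarray:
    """Indices of the K negative classes with largest agent similarity.

    Sorted descending by similarity for each sample; the sample's own class
    is excluded and K is clamped to Y-1.
    """
    sims = value_of(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n, Y = sims.shape
    if Y < 2:
        raise ValueError("need at least 2 classes to form negative agents")
    if k > Y - 1:
        warnings.warn(f"k_neg={k} clamped to Y-1={Y - 1}", stacklevel=2)
        k = Y - 1
    masked = sims.copy()
    masked[np.arange(n), labels] = -np.inf
    order = np.argsort(-masked, axis=1, kind="stable")
    return order[:, :k]


def knnat_loss(logits, labels, k: int, margin: float, per_sample: bool = False):
    """K-nearest-negative-agent triplet hinge on cosine logits.

    Batch mean over samples of ``sum_k max(0, s_neg_k - s_pos + margin)``
    where the k negatives are the nearest (most similar) negative classes.
    """
    labels = np.asarray(labels, dtype=np.intp)
    neg_idx = knn_negative_agents(logits, labels, k)
    n = neg_idx.shape[0]
    rows = np.arange(n)
    pos = logits[rows, labels].reshape((n, 1))
    neg = logits[rows.reshape(-1, 1), neg_idx]
    hinge = tsum(maximum(neg - pos + margin, 0.0), axis=1)
    return hinge if per_sample else tmean(hinge)


def mca_loss(feats, bank, cfg: MCAConfig, labels=None) -> LossBreakdown:
    """The joint multi-center agent objective.

    ``total = softmax_term + tau * reg_term + beta * triplet_term``.
    With ``beta = 0`` this is exactly the (multi-center) SoftMax loss; with
    ``C = 1`` agents coincide with the single centers.
    """
    f, y, agents, logits = _agent_state(feats, labels, bank, cfg.gamma)
    if cfg.renormalize_agents:
        norms = sqrt(tsum(agents * agents, axis=-1, keepdims=True))
        logits = agent_logits(f, agents / norms)
    ce = _cross_entropy(logits * cfg.lam, y)
    if not np.all(np.isfinite(value_of(ce))):
        bad = int(np.flatnonzero(~np.isfinite(value_of(ce)))[0])
        raise FloatingPointError(f"non-finite loss at batch index {bad}")
    softmax_term = tmean(ce)
    reg_term = center_diversity_reg(bank)
    triplet_term = knnat_loss(logits, y, cfg.k_neg, cfg.margin) if cfg.beta > 0 else (
        knnat_loss(logits, y, cfg.k_neg, cfg.margin) * 0.0 if ad.is_tensor(logits) else 0.0
    )
    total = softmax_term + cfg.tau * reg_term + cfg.beta * triplet_term
    return LossBreakdown(total, softmax_term, reg_term, triplet_term, cfg.tau, cfg.beta)


def per_sample_mca_loss(feats, bank, cfg: MCAConfig, labels=None) -> np.ndarray:
    """Per-sample loss ``ce_i + beta*triplet_i``.

    The center-diversity regularizer is a property of the center bank, not
    of any sample, so it is excluded here: the separation guarantees audited
    by :func:`margin_audit` rest only on the sample-dependent terms, and
    charging a global constant to every sample would merely shrink the
    audited set without changing the geometry.
    """
    f, y, _, logits = _agent_state(feats, labels, bank, cfg.gamma)
    ce = value_of(_cross_entropy(value_of(logits) * cfg.lam, y))
    trip = value_of(knnat_loss(value_of(logits), y, cfg.k_neg, cfg.margin, per_sample=True))
    return ce + cfg.beta * trip


# --------------------------------------------------------------------------
# Theorem-based margin audits
# --------------------------------------------------------------------------

@dataclass
class MarginAuditReport:
    """Separation guarantees checked on samples whose loss is below delta0.

    The bounds are implications ("if the per-sample loss is small then the
    geometry is separated"); samples at or above the loss threshold pass
    vacuously and are excluded.
    """

    delta0: float
    qualifying: np.ndarray          # indices with per-sample loss < delta0
    cosine_gaps: np.ndarray         # per qualifying sample: min_j (f.A_y - f.A_j)
    gap_bound: float                # margin - delta0
    t1_pass: bool
    t1_violations: np.ndarray
    min_agent_distance: float       # min over qualifying samples/negatives of ||A_j - A_y||
    agent_distance_bound: float     # 2*(margin - delta0), the squared-distance reading
    t2_sq_pass: bool                # squared distances meet the bound
    t2_triangle_pass: bool          # ||A_j - A_y|| >= ||f - A_j|| - ||f - A_y||
    theta: float                    # empirical intra-class radius max ||f - A_y||
    t3_bound: float                 # margin - delta0 - 2*theta

    @property
    def all_pass(self) -> bool:
        return self.t1_pass and self.t2_sq_pass and self.t2_triangle_pass


def margin_audit(feats, bank, cfg: MCAConfig, delta0: float, labels=None) -> MarginAuditReport:
    """Audit the separation implied by a small loss value.

    For every sample with per-sample loss below ``delta0`` the audit checks
    (T1) the worst positive-minus-negative agent cosine gap exceeds
    ``margin - delta0`` over *all* negatives, (T2) positive/negative agent
    distances against both the squared-distance bound ``2*(margin-delta0)``
    and the triangle-inequality consistency, and (T3) reports the empirical
    intra-class radius ``theta`` and the implied cross-class feature
    similarity gap ``margin - delta0 - 2*theta``.  Failed checks are
    reported, never raised.
    """
    if delta0 <= 0:
        raise ValueError("delta0 must be positive")
    f, y = _as_feats_labels(feats, labels)
    f = value_of(f)
    losses = per_sample_mca_loss(f, bank, cfg, y)
    _, _, agents, logits = _agent_state(f, y, bank, cfg.gamma)
    agents, logits = value_of(agents), value_of(logits)
    n, Y = logits.shape
    rows = np.arange(n)
    qual = np.flatnonzero(losses < delta0)
    bound = cfg.margin - delta0

    neg_mask = np.ones((n, Y), dtype=bool)
    neg_mask[rows, y] = False
    gaps_all = logits[rows, y][:, None] - logits  # f.A_y - f.A_j
    worst_gap = np.where(neg_mask, gaps_all, np.inf).min(axis=1)

    cosine_gaps = worst_gap[qual]
    t1_viol = qual[cosine_gaps <= bound]

    pos_agent = agents[rows, y]                                   # (n, d)
    agent_dists = np.linalg.norm(agents - pos_agent[:, None, :], axis=-1)  # (n, Y)
    feat_dists = np.linalg.norm(agents - f[:, None, :], axis=-1)           # (n, Y)
    pos_feat_dist = feat_dists[rows, y]

    if qual.size:
        q_neg = neg_mask[qual]
        min_agent_dist = float(np.min(agent_dists[qual][q_neg]))
        sq_ok = bool(np.all(agent_dists[qual][q_neg] ** 2 >= 2 * bound - 1e-9))
        tri = agent_dists[qual] - (feat_dists[qual] - pos_feat_dist[qual][:, None])
        tri_ok = bool(np.all(tri[q_neg] >= -1e-9))
        theta = float(np.max(pos_feat_dist[qual]))
    else:
        min_agent_dist, sq_ok, tri_ok, theta = np.inf, True, True, 0.0

    return MarginAuditReport(
        delta0=delta0,
        qualifying=qual,
        cosine_gaps=cosine_gaps,
        gap_bound=bound,
        t1_pass=t1_viol.size == 0,
        t1_violations=t1_viol,
        min_agent_distance=min_agent_dist,
        agent_distance_bound=2 * bound,
        t2_sq_pass=sq_ok,
        t2_triangle_pass=tri_ok,
        theta=theta,
        t3_bound=bound - 2 * theta,
    )


# --------------------------------------------------------------------------
# Baseline losses
# --------------------------------------------------------------------------

def triplet_hard_mining_loss(feats, margin: float = 0.5, labels=None):
    """Sample-level batch-hard triplet loss on Euclidean distances.

    For every anchor with at least one same-class partner in the batch:
    ``max(0, d(a, hardest positive) - d(a, hardest negative) + margin)``
    where the hardest positive is the farthest same-class sample and the
    hardest negative the closest other-class sample.  Anchors without a
    positive are skipped; with no valid anchor the loss is defined as 0.
    """
    f, y = _as_feats_labels(feats, labels)
    n = value_of(f).shape[0]
    d = value_of(f).shape[1]
    diff = f.reshape((n, 1, d)) - f.reshape((1, n, d))
    dists = sqrt(tsum(diff * diff, axis=-1) + _SQRT_EPS)
    same = y[:, None] == y[None, :]
    pos_mask = same & ~np.eye(n, dtype=bool)
    neg_mask = ~same
    valid = pos_mask.any(axis=1) & neg_mask.any(axis=1)
    if not valid.any():
        warnings.warn("no valid triplet anchor in batch; loss is 0", stacklevel=2)
        return 0.0 if not ad.is_tensor(f) else dists.sum() * 0.0
    dvals = value_of(dists)
    hardest_pos = np.where(pos_mask, dvals, -np.inf).argmax(axis=1)
    hardest_neg = np.where(neg_mask, dvals, np.inf).argmin(axis=1)
    rows = np.flatnonzero(valid)
    d_ap = dists[rows, hardest_pos[valid]]
    d_an = dists[rows, hardest_neg[valid]]
    return tmean(maximum(d_ap - d_an + margin, 0.0))


def arcface_loss(feats, bank, m: float = 0.1, r: float = 32.0, labels=None):
    """Additive angular margin softmax on single-center cosine logits.

    The true-class angle is increased by ``m`` radians before the scaled
    softmax; angles are clamped so the penalized angle stays in [0, pi].
    Requires one center per class.
    """
    if isinstance(bank, CenterBank) and bank.centers_per_class != 1:
        raise ValueError("additive angular margin requires a single center per class")
    if m < 0 or r <= 0:
        raise ValueError("need m >= 0 and r > 0")
    f, y = _as_feats_labels(feats, labels)
    cos_all = center_similarities(f, bank)       # (n, Y, 1)
    n, Y, _ = value_of(cos_all).shape
    cos_all = cos_all.reshape((n, Y)) if hasattr(cos_all, "reshape") else cos_all
    cos_all = clip(cos_all, -1.0 + 1e-12, 1.0 - 1e-12)
    theta = arccos(cos_all)
    rows = np.arange(n)
    theta_y = clip(theta[rows, y], 0.0, np.pi - m)
    margin_logit = cos(theta_y + m)
    onehot = np.zeros((n, Y))
    onehot[rows, y] = 1.0
    delta = margin_logit - cos_all[rows, y]
    logits = cos_all + onehot * delta.reshape((n, 1))
    return tmean(_cross_entropy(logits * r, y))


def softtriple_loss(feats, bank, cfg: SoftTripleConfig = SoftTripleConfig(), labels=None):
    """SoftTriple objective: relaxed multi-center similarity with a margin
    subtracted from the true-class logit, plus the center-diversity
    regularizer.  With margin 0 it coincides with the multi-center SoftMax
    term of the joint objective at the same temperature."""
    f, y, _, logits = _agent_state(feats, labels, bank, cfg.gamma)
    n, Y = value_of(logits).shape
    onehot = np.zeros((n, Y))
    onehot[np.arange(n), y] = 1.0
    ce = _cross_entropy((logits - onehot * cfg.margin) * cfg.lam, y)
    return tmean(ce) + cfg.tau * center_diversity_reg(bank)
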