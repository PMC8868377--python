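# Methods

This note documents the model implemented by `mcagent`, the numerical and
design choices behind it, what the synthetic benchmark does and does not
emulate, and the known limitations of both.

## Model

Embeddings and class centers are constrained to the unit hypersphere; all
similarities are inner products (cosines). Class `j` owns `C` centers
`W_j^c`. For a sample `i`, the similarity to class `j` is ideally the
best-matching center, `max_c f_i·W_j^c`; the loss replaces this hard max
by its entropy-smoothed version, whose optimizer has the closed form

    p_ijc ∝ exp(f_i·W_j^c / γ),

and builds the per-sample, per-class **agent** `A_ij = Σ_c p_ijc W_j^c`.
Agents are computed for *every* class (not only the true one) because the
SoftMax denominator needs the logits `f_i·A_ij` of all classes. As
`γ → 0+` the agent logit converges monotonically to the hard max; as
`γ → ∞` the assignment tends to uniform `1/C`. Both limits are property-
tested.

The objective has three parts:

1. **SoftMax over agent logits**, scaled by `λ` (the radius of the
   product sphere; without it, normalized logits in [−1, 1] produce
   vanishing gradients). Batch reduction is the arithmetic mean, keeping
   hyperparameters batch-size independent.
2. **Center-diversity regularizer**: the L2,1 norm of pairwise
   differences of same-class centers, over ordered pairs, normalized by
   `Y·C·(C−1)`; zero for `C=1`. Its role is to merge *redundant* centers
   when `C` over-provisions the true number of local clusters.
3. **K-nearest-negative-agent triplet**: a hinge `max(0, f·A_k − f·A_y + Δ)`
   summed over the `K` negative classes with the largest agent similarity
   to the anchor. Because the negatives are the nearest ones, a small
   triplet value bounds the gap to *all* negatives — implicit
   hard-negative mining without any sampling machinery.

Defaults: `λ=24, τ=0.2, γ=0.1, C=10, Δ=0.4, K=2, β=0.1`; `K` is clamped
to `Y−1` with a warning when few classes are present. The hinge operates
on raw agent inner products: agents are convex combinations and have norm
≤ 1, so the exact Euclidean↔cosine rewriting (valid for unit vectors)
is approximate for agents; renormalizing agents is available as an
off-by-default option (`MCAConfig.renormalize_agents`). A single `γ` is
used for the true and negative classes.

### Separation audit

If a sample's loss is small, its geometry is provably separated; the
audit (`margin_audit`) makes this checkable on any trained state. The
per-sample loss used for qualification is `CE_i + β·trip_i` — the
center regularizer is a property of the center bank, not of a sample, and
charging the whole-bank value to each sample would only shrink the
audited set without changing the geometry. For every sample below the
threshold `δ0` the audit checks:

* **T1**: the worst cosine gap `min_{j≠y}(f·A_y − f·A_j)` exceeds
  `Δ − δ0`. Strictly, a loss below `δ0` bounds the *weighted* triplet
  term `β·trip_i`, so the audited bound is conservative when `β < 1`;
  the audit reports violations rather than asserting, and on converged
  states the gaps sit at the full margin `Δ` anyway.
* **T2**: positive/negative agent distances, in both readings — the
  squared-distance bound `‖A_j − A_y‖² ≥ 2(Δ − δ0)` implied by the
  cosine gap, and the triangle-inequality consistency
  `‖A_j − A_y‖ ≥ ‖f − A_j‖ − ‖f − A_y‖`. (The two readings differ
  because the distance/squared-distance conversion is not interchangeable;
  the audit reports both rather than asserting the stronger claim.)
* **T3**: the empirical intra-class radius `θ = max ‖f − A_y‖` and the
  implied cross-class feature-similarity gap `Δ − δ0 − 2θ`.

Samples at or above `δ0` pass vacuously (the theorems are implications).

### Baselines

For controlled comparisons the package ships, behind the same training
interface: the sample-level batch-hard triplet loss (Euclidean distances,
farthest positive and closest negative per anchor, margin 0.5, with a
class-aware batch sampler because it needs positives in-batch), additive
angular margin SoftMax (margin 0.1 on the true-class angle, scale 32,
single center), and SoftTriple (`λ=24, γ=0.05, τ=0.2, C=10`, margin 0.01
subtracted from the true-class logit). With margin 0, SoftTriple
coincides with the multi-center SoftMax term at the same temperature —
a tested reduction.

## Optimization

A single Adam optimizer (lr 1e-3, exponential decay 0.95 per epoch)
updates backbone and centers jointly; features are re-normalized before
every loss call and centers on every read, so the unit-norm invariants
hold under any update. The autodiff core is a compact reverse-mode tape
over NumPy arrays; its gradients are verified against central finite
differences both op-by-op and through the full joint loss.

**Center initialization.** Centers are warm-started by per-class k-means
('++' seeding) on the embeddings of the untrained backbone, with a small
random perturbation, then trained jointly. Two failure modes of naive
initialization motivated this: symmetric random centers admit a merged
fixed point (the assignment stays uniform, the center pair settles at the
between-cluster bisector and nothing breaks the tie), and initializing at
random class samples leaves some local cluster uncovered with probability
`~(1/M)^(C−1)` per class. Data-driven proxy initialization is standard
practice for center-based losses.

**A desk-scale caveat worth knowing.** The regularizer's normalizer
`Y·C·(C−1)` is ~4500 at the scale the loss was designed for (tens of
classes, `C=10`) but only 8 in the small recovery experiments below
(`Y=4, C=2`), making the merge-pull on centers orders of magnitude
stronger relative to the margin terms, which saturate once the gap
exceeds `≈ ln(λ(Y−1))/λ`. Asymptotically the centers of a class would
merge; the finite 200-epoch protocol (matching the reference protocol)
ends training long before that creep matters. This is documented rather
than "fixed" because it is a faithful property of the objective at small
`Y·C`.

## Synthetic benchmark

The generator emulates the statistical signature of multi-view identity
data: each class is a mixture of `M` tight clusters ("views") on the unit
sphere. Per class, `M` unit directions are rejection-sampled in a latent
space under a pairwise-angle floor (default 60°); samples are the
directions plus isotropic Gaussian noise, re-normalized, and carried into
the raw input space by one seeded orthogonal map shared by all classes
(so the problem is nontrivial but solvable by a small linear backbone).
Everything is a pure function of the spec, including its seed.

Default spec (`SyntheticSpec()`): 4 classes × 100 samples, `M=2`,
`σ=0.02`, latent dim 8, input dim 32 — the conditions of the
center-recovery experiment. The generator deliberately plants same-class
clusters at *large* mutual angles so that representing a class by one
center is costly and the value of multiple centers is measurable.

What it does **not** emulate: pixel statistics, illumination, pose
continuity (views are discrete), class imbalance, label noise, detector
crops, or a shared "view transform" across identities (each class's view
directions are independent). Success on this benchmark shows the loss
does what it claims *given* clusterable features; it says nothing about
whether a particular convolutional backbone can produce such features
from photographs. The optional pattern-image mode (thresholded
smoothed-noise blobs with per-view geometric variants) exists to exercise
image-input code paths, not to imitate animal imagery.

## Study conditions used by the tests and acceptance script

* **Center recovery** — default spec, `C=M=2`, full-batch Adam for 200
  epochs, embedding dim 8. The learned centers match the embedded planted
  view directions with cosine ≥ 0.9 after optimal (Hungarian) matching,
  across seeds. Full-batch is used deliberately: coherent gradients and a
  bounded step count keep the regularizer creep (above) negligible.
* **Separation audit** — easy planted data (4 classes × 50, `σ=0.02`),
  full-batch, 200 epochs: every per-sample loss falls below `δ0=0.1` and
  the triplet pushes every cosine gap past `Δ=0.4`, so the T1 check
  (bound 0.3) passes with zero violations, non-vacuously.
* **Ablation ordering** — 12 identities × 24 samples, `M=2`, latent dim
  3, `σ=0.1`, angle floor 120°, embedding dim 6, batch 32, 200 epochs,
  two-fold open-set CV with k=5 and paired seeds. The crowded 3-d latent
  is essential: with many well-separated classes every variant saturates
  its margin without reshaping the embedding, and the ablations tie at
  the separability of the raw data. With 24 view-directions crowding a
  3-sphere, the class-mean representation is structurally lossy and the
  ordering (multi-center ≥ single-center, full loss > single-center in
  the mean) emerges; at this scale the β=0.1 triplet typically ties the
  β=0 ablation rather than strictly improving it.
* **Chance calibration** — randomized gallery labels; k-NN accuracy must
  land in the 99% binomial interval around `1/(enrolled identities)`.

Problem sizes were chosen so the whole suite and the acceptance script
each run in about half a minute on one CPU.

## Known limitations

* The backbone zoo is intentionally small (linear/dense, a small
  convolution, external plug-ins); no pretrained networks are bundled.
* The triplet term's contribution at few-class, low-dimension scale is
  often within the discretization of k-NN accuracy; its effect is visible
  in the loss decomposition, not always in accuracy.
* Open-set evaluation enrolls unseen identities only; verification-style
  metrics (ROC/CMC) are out of scope.
* `min/max` in reports are per-fold extremes, not across repeated runs.
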