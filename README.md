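# mcagent — multi-center agent metric learning for open-set animal identification

`mcagent` implements a proxy-based deep-metric-learning objective for
visually identifying individual animals (e.g. cattle with individually
characteristic coat markings) under the **open-set protocol**: the
identities encountered at test time were never seen during representation
learning, and classification happens by *k*-nearest-neighbour voting
against an enrolled gallery of embeddings.

The difficulty the method targets is the structure of multi-view identity
data: the same animal photographed from the front, back, left or right
forms **several distinct local clusters** in feature space, while different
animals seen from the same viewpoint can look confusingly alike. A single
class center (as in NormFace/ArcFace-style losses) cannot represent a
multi-cluster class well.

## The loss

Features `f_i` and all centers live on the unit hypersphere. Each class
`j` owns `C` trainable centers `W_j^c`. The **agent** of class `j` for
sample `i` is the entropy-regularized convex combination

    p_ijc = softmax_c( f_i · W_j^c / γ ),     A_ij = Σ_c p_ijc · W_j^c,

the closed-form solution of the smoothed max-similarity program
(`γ → 0` recovers `max_c f_i · W_j^c`). The joint objective is

    L = mean_i [ −log  e^{λ f_i·A_iy} / Σ_j e^{λ f_i·A_ij} ]      (SoftMax over agents)
      + τ · Σ_j Σ_t ‖S_j^t‖_{2,1} / (Y·C·(C−1))                   (center diversity, L2,1)
      + β · mean_i Σ_{k ∈ NN_K(i)} max(0, f_i·A_ik − f_i·A_iy + Δ) (K-nearest-negative-agent triplet)

with defaults `λ=24, τ=0.2, γ=0.1, C=10, Δ=0.4, K=2, β=0.1`. The triplet
term is an implicit hard-negative mining over proxies: only the `K`
negative classes whose agents are most similar to the anchor contribute.
Setting `C=1` and/or `β=0` recovers the whole ablation family
(single-center SoftMax, multi-center SoftMax, single-center agent loss)
from the same code path.

The package contains, fully tested:

* `core_geometry` — hypersphere primitives (normalization, similarities,
  assignment distribution, agents, logits);
* `mca_losses` — the joint objective, its per-sample separation audit
  (small loss ⇒ provable cosine gaps between positive and negative
  agents), and the comparison baselines (batch-hard triplet, additive
  angular margin, SoftTriple), all differentiable through a small
  reverse-mode autodiff core (`autodiff`);
* `synthetic_data` — a seeded generator planting multi-cluster classes on
  the unit sphere (plus a procedural pattern-image mode), so everything is
  trainable and verifiable without external data;
* `training` — Adam (lr 1e-3, exponential decay 0.95/epoch), joint
  optimization of a pluggable backbone and the center bank, k-means
  warm-started centers, checkpoints;
* `openset_eval` — identity-disjoint two-fold cross-validation, 7:3
  gallery/query splits, k-NN (k=5) classification, reports in the
  `average:[min, max]` accuracy format;
* `cli_io` — a `mcagent` command-line front end (`simulate`, `train`,
  `evaluate`, `audit`, `sweep-centers`, `compare-losses`) with strict YAML
  configuration.

## Worked example

```python
import mcagent as mc

# 12 identities, 2 view-clusters each, crowded 3-d latent sphere
spec = mc.SyntheticSpec(num_classes=12, clusters_per_class=2, samples_per_class=24,
                        latent_dim=3, input_dim=12, noise=0.1,
                        min_cluster_angle=120.0, seed=101)
ds = mc.generate_multicluster_vectors(spec)

stats = mc.cluster_separation_stats(ds)
print(f"within-cluster cosine      {stats.within_cluster:.3f}")
print(f"cross-cluster (same class) {stats.within_class_cross_cluster:.3f}")
print(f"cross-class cosine         {stats.cross_class:.3f}")

train_cfg = mc.TrainConfig(epochs=200, batch_size=32, embed_dim=6, seed=1)
report = mc.twofold_cross_validate(ds, train_cfg, mc.MCAConfig(centers_per_class=2),
                                   k=5, seed=1)
print(report)
baseline = mc.twofold_cross_validate(ds, train_cfg,
                                     mc.MCAConfig(centers_per_class=1, beta=0.0),
                                     k=5, seed=1)
print(baseline)
```

prints

```
within-cluster cosine      0.979
cross-cluster (same class) -0.693
cross-class cosine         -0.002
Average Accuracy (%):[Minimum, Maximum] = 90.48:[85.71, 95.24]
Average Accuracy (%):[Minimum, Maximum] = 89.29:[83.33, 95.24]
```

Reading: samples of the same view-cluster are nearly parallel (0.979),
the two views of one identity point in very different directions (−0.69 —
large intra-class variance), and different identities are uncorrelated on
average. Trained and evaluated on identities never seen in training, the
multi-center agent loss reaches 90.48% mean two-fold accuracy versus
89.29% for the single-center SoftMax ablation on the same data and seeds.

The same experiment from the shell:

```bash
mcagent simulate --config config.yaml --out runs/data
mcagent evaluate --config config.yaml --out runs/eval
mcagent audit    --config config.yaml --out runs/audit --delta0 0.1
```

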