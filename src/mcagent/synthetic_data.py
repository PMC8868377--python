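"""Seeded synthetic datasets with planted multi-cluster class structure.

Real multi-view animal-identification data has a characteristic shape:
every individual is photographed from several viewpoints, so one identity
occupies *several tight local clusters* in feature space, while different
individuals can look alike from the same viewpoint.  The vector generator
plants exactly that structure on the unit sphere: each class receives M
unit "view" directions kept at least ``min_cluster_angle`` apart by
rejection sampling, samples scatter around their view direction with
isotropic Gaussian noise, and a single seeded orthogonal map (shared by
all classes) embeds the latent sphere into the raw input space.  Because
same-class clusters sit at large mutual angles, a single class center is a
poor summary and the benefit of multiple centers becomes measurable.

An optional image mode renders each class as a thresholded smoothed-noise
blob pattern (a cartoon of individually characteristic coat markings) with
per-view geometric variants, for exercising image-input code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "SeparationStats",
    "generate_multicluster_vectors",
    "generate_pattern_images",
    "cluster_separation_stats",
    "write_vector_dataset",
    "read_vector_dataset",
    "write_image_dataset",
]

_MAX_REJECTION_TRIES = 10_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted multi-cluster generator.

    Defaults describe a small but non-trivial open-set problem: 4 classes
    of 100 samples, each split over 2 view clusters at >= 60 degrees
    mutual angle, tight within-cluster noise (sigma = 0.02) and a 32-d raw
    input embedding an 8-d latent sphere.
    """

    num_classes: int = 4
    clusters_per_class: int = 2
    samples_per_class: int = 100
    latent_dim: int = 8
    input_dim: int = 32
    noise: float = 0.02
    min_cluster_angle: float = 60.0  # degrees, between same-class cluster directions
    seed: int = 0

    def __post_init__(self):
        if self.clusters_per_class < 1:
            raise ValueError("clusters_per_class must be >= 1")
        if self.samples_per_class < self.clusters_per_class:
            raise ValueError("samples_per_class must be >= clusters_per_class")
        if self.input_dim < self.latent_dim:
            raise ValueError("input_dim must be >= latent_dim")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class SyntheticDataset:
    """Generated samples plus the planted ground truth."""

    vectors: np.ndarray          # (n, input_dim) unit rows
    labels: np.ndarray           # (n,) class indices
    cluster_ids: np.ndarray      # (n,) planted view-cluster per sample
    directions: np.ndarray       # (Y, M, latent_dim) planted unit directions
    embed_map: np.ndarray        # (input_dim, latent_dim) orthonormal columns
    spec: SyntheticSpec

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def mapped_directions(self) -> np.ndarray:
        """Planted directions carried into raw input space, (Y, M, input_dim)."""
        return self.directions @ self.embed_map.T


def _sample_directions(rng: np.random.Generator, m: int, dim: int, min_angle_deg: float):
    """Rejection-sample m unit vectors with pairwise angle >= min_angle."""
    cos_max = np.cos(np.radians(min_angle_deg))
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < m:
        if tries >= _MAX_REJECTION_TRIES:
            raise ValueError(
                f"could not place {m} directions at >= {min_angle_deg} deg in "
                f"{dim}-d after {_MAX_REJECTION_TRIES} tries; relax the angle"
            )
        tries += 1
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        if all(float(v @ u) <= cos_max for u in dirs):
            dirs.append(v)
    return np.stack(dirs)


def generate_multicluster_vectors(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the planted dataset; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    Y, M, nc = spec.num_classes, spec.clusters_per_class, spec.samples_per_class
    directions = np.stack(
        [_sample_directions(rng, M, spec.latent_dim, spec.min_cluster_angle) for _ in range(Y)]
    )
    # one orthogonal embedding shared across classes
    gauss = rng.standard_normal((spec.input_dim, spec.latent_dim))
    q, _ = np.linalg.qr(gauss)
    vectors, labels, clusters = [], [], []
    for j in range(Y):
        cluster_of = np.arange(nc) % M  # round-robin: every cluster non-empty
        noise = rng.standard_normal((nc, spec.latent_dim)) * spec.noise
        latent = directions[j][cluster_of] + noise
        latent /= np.linalg.norm(latent, axis=1, keepdims=True)
        vectors.append(latent @ q.T)
        labels.append(np.full(nc, j))
        clusters.append(cluster_of)
    return SyntheticDataset(
        vectors=np.concatenate(vectors),
        labels=np.concatenate(labels),
        cluster_ids=np.concatenate(clusters),
        directions=directions,
        embed_map=q,
        spec=spec,
    )


def generate_pattern_images(spec: SyntheticSpec, image_size: int = 32):
    """Procedural blob-pattern images: one base pattern per class, one
    geometric variant per view cluster, plus per-sample pixel noise.

    Returns ``(images, labels, cluster_ids)`` with images in [0, 1],
    shape (n, image_size, image_size), deterministic per seed.
    """
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    rng = np.random.default_rng(spec.seed)
    Y, M, nc = spec.num_classes, spec.clusters_per_class, spec.samples_per_class
    images, labels, clusters = [], [], []
    for j in range(Y):
        base = gaussian_filter(rng.standard_normal((image_size, image_size)), image_size / 8.0)
        pattern = (base > np.median(base)).astype(float)
        variants = []
        for m in range(M):
            v = np.rot90(pattern, k=m % 4)
            if (m // 4) % 2:
                v = np.flipud(v)
            dx, dy = rng.integers(-image_size // 8, image_size // 8 + 1, size=2)
            variants.append(nd_shift(v, (dx, dy), order=0, mode="wrap"))
        cluster_of = np.arange(nc) % M
        for i in range(nc):
            img = variants[cluster_of[i]] + rng.standard_normal((image_size, image_size)) * spec.noise
            images.append(np.clip(img, 0.0, 1.0))
        labels.append(np.full(nc, j))
        clusters.append(cluster_of)
    return np.stack(images), np.concatenate(labels), np.concatenate(clusters)


@dataclass
class SeparationStats:
    """Mean pairwise cosines over exhaustive pair sets; None when a set is empty."""

    within_cluster: Optional[float]
    within_class_cross_cluster: Optional[float]
    cross_class: Optional[float]


def cluster_separation_stats(ds: SyntheticDataset) -> SeparationStats:
    """Exhaustive pairwise cosine summary of the planted structure."""
    g = ds.vectors @ ds.vectors.T
    same_class = ds.labels[:, None] == ds.labels[None, :]
    same_cluster = same_class & (ds.cluster_ids[:, None] == ds.cluster_ids[None, :])
    upper = np.triu(np.ones_like(same_class, dtype=bool), k=1)

    def mean_over(mask):
        m = mask & upper
        return float(g[m].mean()) if m.any() else None

    return SeparationStats(
        within_cluster=mean_over(same_cluster),
        within_class_cross_cluster=mean_over(same_class & ~same_cluster),
        cross_class=mean_over(~same_class),
    )


# --------------------------------------------------------------------------
# Plain-text persistence (delimited with header: id, label, cluster, x1..xD)
# --------------------------------------------------------------------------

def write_vector_dataset(ds: SyntheticDataset, path) -> None:
    import pandas as pd

    d = ds.vectors.shape[1]
    frame = pd.DataFrame(ds.vectors, columns=[f"x{i + 1}" for i in range(d)])
    frame.insert(0, "cluster", ds.cluster_ids)
    frame.insert(0, "label", ds.labels)
    frame.insert(0, "id", np.arange(ds.n))
    frame.to_csv(path, index=False)


def read_vector_dataset(path):
    """Read a written vector dataset; returns (vectors, labels, cluster_ids)."""
    import pandas as pd

    frame = pd.read_csv(path)
    for col in ("id", "label", "cluster"):
        if col not in frame.columns:
            raise ValueError(f"dataset file {path} is missing required column '{col}'")
    xcols = [c for c in frame.columns if c.startswith("x")]
    return (
        frame[xcols].to_numpy(dtype=float),
        frame["label"].to_numpy(dtype=np.intp),
        frame["cluster"].to_numpy(dtype=np.intp),
    )


def write_image_dataset(images, labels, out_dir) -> None:
    """Write images as PNGs in a class-per-directory layout."""
    from PIL import Image

    out = Path(out_dir)
    for j in np.unique(labels):
        (out / f"class_{j:03d}").mkdir(parents=True, exist_ok=True)
    counters: dict[int, int] = {}
    for img, lab in zip(images, labels):
        k = counters.get(int(lab), 0)
        counters[int(lab)] = k + 1
        arr = (np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / f"class_{int(lab):03d}" / f"img_{k:04d}.png")
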