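"""Deterministic generators of microarray-like two-class datasets.

``generate`` emulates the *shape* of a classic two-class leukemia
expression study: far more genes than samples (default 500 × 72, with a
7129-gene "paper shape" available), an imbalanced 47/25 class split, a
small set of truly informative genes whose expression is mean-shifted in
the minority class, and sporadic missing values.  The generative model is
simple by design — per-gene Gaussian baselines plus i.i.d. Gaussian noise
— which is what makes recovery experiments interpretable; it does not
model probe effects, batch effects or heavy-tailed noise.

``generate_blobs`` makes isotropic Gaussian clusters with a prescribed
mutual centre distance, the canonical fixture for subtractive-clustering
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the expression-matrix generator.

    ``effect_size`` is the informative-gene mean shift in units of the
    within-class noise standard deviation ``noise_sd``.
    """

    n_samples: int = 72
    n_genes: int = 500
    class_sizes: tuple[int, int] = (47, 25)
    n_informative: int = 10
    effect_size: float = 3.0
    missing_rate: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.class_sizes) < 1:
            raise ValueError("both class sizes must be positive")
        if sum(self.class_sizes) != self.n_samples:
            raise ValueError("class sizes must sum to n_samples")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Expression matrix, labels and the list of truly informative gene ids.

    Class-0 samples come first.  Informative genes gain
    ``effect_size · noise_sd`` in class 1.  Missing entries are planted
    uniformly at ``missing_rate`` but never wipe out a whole gene.
    Bit-identical for a fixed spec (one private RNG stream per call).
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    n0, n1 = spec.class_sizes
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])

    baseline = rng.normal(7.0, 2.0, size=g)  # per-gene expression level
    values = baseline[None, :] + rng.normal(0.0, spec.noise_sd, size=(n, g))
    informative = np.sort(rng.choice(g, size=spec.n_informative, replace=False))
    values[np.ix_(labels == 1, informative)] += spec.effect_size * spec.noise_sd

    if spec.missing_rate > 0:
        mask = rng.random(size=(n, g)) < spec.missing_rate
        full = mask.all(axis=0)
        if full.any():  # keep at least one observation per gene
            keep_rows = rng.integers(0, n, size=int(full.sum()))
            mask[keep_rows, np.flatnonzero(full)] = False
        values = np.where(mask, np.nan, values)

    gene_ids = [f"g{i + 1:04d}" for i in range(g)]
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(values, index=sample_ids, columns=gene_ids)
    truth = [gene_ids[i] for i in informative]
    return frame, pd.Series(labels, index=sample_ids, name="label"), truth


def generate_blobs(
    n_clusters: int,
    points_per_cluster: int,
    separation: float,
    dim: int = 2,
    seed: int = 0,
    cluster_sd: float = 0.05,
) -> np.ndarray:
    """Isotropic Gaussian clusters whose centres are mutually ``separation`` apart.

    Centres sit at scaled standard-basis vectors (pairwise distance is then
    exactly ``separation``), which requires ``dim >= n_clusters`` for more
    than one cluster.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_clusters > 1 and dim < n_clusters:
        raise ValueError("dim must be >= n_clusters for equidistant centres")
    rng = np.random.default_rng(seed)
    if n_clusters == 1:
        centers = np.zeros((1, dim))
    else:
        centers = np.eye(dim)[:n_clusters] * (separation / np.sqrt(2.0))
    points = [
        c + rng.normal(0.0, cluster_sd, size=(points_per_cluster, dim))
        for c in centers
    ]
    return np.vstack(points)
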