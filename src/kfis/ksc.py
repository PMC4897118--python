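"""Kernel subtractive clustering (KSC).

Subtractive clustering scores every data point with a *potential* — a sum
of Gaussian-decaying contributions from all points — and greedily selects
high-potential points as cluster centroids, subtracting each winner's
influence before picking the next.  The kernel variant measures all
distances in the feature space of a Mercer kernel, so the potential of
point i is

    p(xᵢ) = Σⱼ exp(−α · d²_φ(xᵢ, xⱼ)),     α = 4 / r_a²,

with d²_φ the kernel squared distance, and after accepting centroid x*
with potential p* every potential is revised

    p(xᵢ) ← p(xᵢ) − p* · exp(−β · d²_φ(xᵢ, x*)),   β = 4 / r_b²,

where r_b = η·r_a widens the suppression neighbourhood.  Acceptance uses
the classic accept/reject thresholds: a candidate with remaining potential
p* is accepted outright when p* > ε·p₁*, the loop stops when p* < ε̄·p₁*,
and in the grey zone between the candidate is accepted only if
d_min/r_a + p*/p₁* ≥ 1 (d_min = feature-space distance to the nearest
accepted centroid), otherwise its potential is zeroed and the search
continues.  With the linear kernel the procedure reduces exactly to
classic (input-space) subtractive clustering.

Membership widths use the standard convention σ = r_a · range / √8 per
feature, i.e. σ = r_a/√8 on data normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, gram_matrix, sq_distance_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSCParams:
    """Subtractive-clustering hyperparameters.

    ``cluster_radius`` (r_a) is the neighbourhood scale in normalized data
    space; ``squash_factor`` (η) widens the revision radius r_b = η·r_a;
    ``accept_ratio`` (ε) and ``reject_ratio`` (ε̄) threshold the potential
    ratio p*/p₁* for outright acceptance and loop termination.
    """

    cluster_radius: float = 0.5
    squash_factor: float = 1.25
    accept_ratio: float = 0.75
    reject_ratio: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.cluster_radius <= 1:
            raise ValueError("cluster_radius must be in (0, 1]")
        if not 1 <= self.squash_factor <= 2:
            raise ValueError("squash_factor must be in [1, 2]")
        if not 0 < self.accept_ratio <= 1:
            raise ValueError("accept_ratio must be in (0, 1]")
        if not 0 < self.reject_ratio <= 1:
            raise ValueError("reject_ratio must be in (0, 1]")
        if not self.reject_ratio < self.accept_ratio:
            raise ValueError("reject_ratio must be below accept_ratio")

    @property
    def revision_radius(self) -> float:
        """r_b = η · r_a."""
        return self.squash_factor * self.cluster_radius

    @property
    def alpha(self) -> float:
        """α = 4 / r_a²."""
        return 4.0 / self.cluster_radius**2

    @property
    def beta(self) -> float:
        """β = 4 / r_b²."""
        return 4.0 / self.revision_radius**2


@dataclass
class ClusterModel:
    """Result of kernel subtractive clustering.

    Centroids are always data points; ``centroid_indices`` records them in
    selection order, the first having the maximal initial potential.
    """

    centroid_indices: list[int]
    centroids: np.ndarray
    sigmas: np.ndarray  # n_rules × n_features, strictly positive
    initial_potentials: np.ndarray
    final_potentials: np.ndarray
    params: KSCParams = field(default_factory=KSCParams)

    @property
    def n_rules(self) -> int:
        return len(self.centroid_indices)


def initial_potentials(G: np.ndarray, params: KSCParams) -> np.ndarray:
    """Potential of every point from a Gram matrix (self-term contributes 1)."""
    return np.exp(-params.alpha * _sqd(G)).sum(axis=1)


def _sqd(G: np.ndarray) -> np.ndarray:
    diag = np.diag(G)
    D2 = diag[:, None] + diag[None, :] - 2.0 * G
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return D2


def revise_potentials(
    p: np.ndarray,
    G: np.ndarray,
    winner: int,
    p_star: float,
    params: KSCParams,
) -> np.ndarray:
    """Subtract the accepted centroid's influence; winner drops to exactly 0."""
    D2 = _sqd(G)
    revised = p - p_star * np.exp(-params.beta * D2[:, winner])
    np.maximum(revised, 0.0, out=revised)
    revised[winner] = 0.0
    return revised


def ksc_cluster(X, spec: KernelSpec, params: KSCParams | None = None) -> ClusterModel:
    """Select rule centroids and widths by kernel subtractive clustering.

    ``X`` is a samples × features matrix, assumed normalized to [0, 1].
    Returns at least one centroid; every centroid is a row of ``X``.
    """
    if params is None:
        params = KSCParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ValueError("empty input")
    G = gram_matrix(spec, X)
    D2 = sq_distance_matrix(spec, G)

    p0 = np.exp(-params.alpha * D2).sum(axis=1)
    p = p0.copy()

    # the global argmax is always the first centroid (ties -> lowest index)
    first = int(np.argmax(p))
    p1_star = float(p[first])
    accepted = [first]
    p = revise_potentials(p, G, first, p1_star, params)

    while True:
        cand = int(np.argmax(p))
        p_star = float(p[cand])
        if p_star <= 0.0:
            break
        ratio = p_star / p1_star
        if p_star > params.accept_ratio * p1_star:
            accept = True
        elif p_star < params.reject_ratio * p1_star:
            break
        else:
            d_min = np.sqrt(D2[cand, accepted].min())
            accept = d_min / params.cluster_radius + ratio >= 1.0
        if accept:
            accepted.append(cand)
            p = revise_potentials(p, G, cand, p_star, params)
        else:
            p[cand] = 0.0  # grey-zone reject: remove from contention

    sigma_row = compute_sigmas(params, X.shape[1])
    sigmas = np.tile(sigma_row, (len(accepted), 1))
    return ClusterModel(
        centroid_indices=accepted,
        centroids=X[accepted].copy(),
        sigmas=sigmas,
        initial_potentials=p0,
        final_potentials=p,
        params=params,
    )


def compute_sigmas(
    params: KSCParams, n_features: int, feature_ranges=None
) -> np.ndarray:
    """Per-feature membership widths σⱼ = r_a · rangeⱼ / √8.

    ``feature_ranges`` defaults to 1 per feature (data normalized to [0, 1]).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if feature_ranges is None:
        feature_ranges = np.ones(n_features)
    feature_ranges = np.asarray(feature_ranges, dtype=float)
    return params.cluster_radius * feature_ranges / np.sqrt(8.0)
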