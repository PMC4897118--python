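"""Kernel Takagi–Sugeno–Kang fuzzy inference classifier (K-FIS).

A fitted model is a rule base.  Rule k owns

* a Gaussian antecedent per feature: membership
  Aⱼᵏ(x) = exp(−d²_K(xⱼ, cⱼᵏ) / (2σⱼᵏ²)), where d²_K is the kernel squared
  distance evaluated on the scalar j-th coordinates,
* a firing strength μₖ(x) = Πⱼ Aⱼᵏ(x) (product t-norm),
* a consequent written as a representer expansion over the stored
  training points: Rᵏ(x) = b₀ᵏ + Σᵢ αᵢᵏ K(xᵢ, x).

The crisp output is the firing-strength-weighted average
Y = Σₖ μₖ Rᵏ / Σₖ μₖ, squashed to a probability ŷ = 1/(1 + e^(−Y)).

Rule centroids and widths come from kernel subtractive clustering; the
consequent coefficients of all rules are estimated jointly by a single
ridge-regularized least-squares solve against logit-scale targets.  The
whole fit is deterministic: no random initialisation anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .kernels import KernelSpec, _pairwise, coordwise_sq_distance, gram_matrix
from .ksc import ClusterModel, KSCParams, compute_sigmas, ksc_cluster

logger = logging.getLogger(__name__)

#: firing strengths whose sum falls below this are replaced by uniform weights
FIRING_FLOOR = 1e-300

#: labels are clipped away from {0, 1} before the logit so targets stay finite
TARGET_CLIP = 0.05


@dataclass
class FuzzyRule:
    """One TSK rule: Gaussian antecedents plus a kernel-expansion consequent."""

    centroid: np.ndarray
    sigma: np.ndarray
    intercept: float
    expansion_coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.expansion_coeffs = np.asarray(self.expansion_coeffs, dtype=float)
        if not (self.sigma > 0).all():
            raise ValueError("rule widths must be strictly positive")


@dataclass
class KFISModel:
    """A fitted kernel fuzzy inference classifier."""

    rules: list[FuzzyRule]
    kernel: KernelSpec
    training_points: np.ndarray
    feature_ids: list = field(default_factory=list)
    normalization_table: pd.DataFrame | None = None
    decision_threshold: float = 0.5
    ksc_params: KSCParams = field(default_factory=KSCParams)
    cluster: ClusterModel | None = None

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    # sklearn-flavoured conveniences
    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self, X)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def membership(rule: FuzzyRule, spec: KernelSpec, x) -> np.ndarray:
    """Per-feature membership degrees Aⱼᵏ(x) ∈ (0, 1]; 1 at the centroid."""
    d2 = coordwise_sq_distance(spec, np.asarray(x, dtype=float), rule.centroid)
    return np.exp(-d2 / (2.0 * rule.sigma**2))


def firing_strength(rule: FuzzyRule, spec: KernelSpec, x) -> float:
    """Product t-norm over the per-feature memberships."""
    return float(np.prod(membership(rule, spec, x)))


def rule_output(rule: FuzzyRule, spec: KernelSpec, x, training_points) -> float:
    """Consequent Rᵏ(x) = b₀ᵏ + Σᵢ αᵢ K(xᵢ, x) over the stored training points."""
    training_points = np.atleast_2d(np.asarray(training_points, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    k = _pairwise(spec, training_points, x[None, :]).ravel()
    return float(rule.intercept + rule.expansion_coeffs @ k)


def _firing_matrix(model: KFISModel, X: np.ndarray) -> np.ndarray:
    """n × R firing strengths."""
    mu = np.empty((X.shape[0], model.n_rules))
    for k, rule in enumerate(model.rules):
        d2 = coordwise_sq_distance(model.kernel, X, rule.centroid)
        mu[:, k] = np.exp(-d2 / (2.0 * rule.sigma**2)).prod(axis=1)
    return mu


def _weights(mu: np.ndarray) -> np.ndarray:
    """Normalized firing strengths; uniform fallback on total underflow."""
    total = mu.sum(axis=1)
    dead = total < FIRING_FLOOR
    if dead.any():
        logger.warning(
            "firing strengths underflowed for %d sample(s); using uniform weights",
            int(dead.sum()),
        )
    w = np.where(dead[:, None], 1.0 / mu.shape[1], mu / np.where(dead, 1.0, total)[:, None])
    return w


def _rule_outputs(model: KFISModel, X: np.ndarray) -> np.ndarray:
    """n × R consequent values via one cross-kernel matrix."""
    Kx = _pairwise(model.kernel, X, model.training_points)  # n × m
    out = np.empty((X.shape[0], model.n_rules))
    for k, rule in enumerate(model.rules):
        out[:, k] = rule.intercept + Kx @ rule.expansion_coeffs
    return out


def _coerce(model: KFISModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if model.feature_ids:
            missing = [g for g in model.feature_ids if g not in X.columns]
            if missing:
                raise ValueError(f"input lacks model feature(s): {missing}")
            X = X[model.feature_ids]
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = model.training_points.shape[1]
    if X.shape[1] != p:
        raise ValueError(f"expected {p} features, got {X.shape[1]}")
    return X


def predict_raw(model: KFISModel, X) -> np.ndarray:
    """Defuzzified output Y — a convex combination of the rule consequents."""
    X = _coerce(model, X)
    w = _weights(_firing_matrix(model, X))
    return (w * _rule_outputs(model, X)).sum(axis=1)


def predict_proba(model: KFISModel, X) -> np.ndarray:
    """ŷ = 1 / (1 + e^(−Y)), strictly inside (0, 1)."""
    return expit(predict_raw(model, X))


def predict(model: KFISModel, X) -> np.ndarray:
    """Class labels: 1 iff ŷ ≥ decision_threshold."""
    return (predict_proba(model, X) >= model.decision_threshold).astype(int)


def fit(
    X,
    y,
    spec: KernelSpec,
    params: KSCParams | None = None,
    ridge: float = 1e-6,
    feature_ids: list | None = None,
    normalization_table: pd.DataFrame | None = None,
    decision_threshold: float = 0.5,
) -> KFISModel:
    """Train a K-FIS classifier on a normalized feature matrix.

    Steps: (1) kernel subtractive clustering chooses R rule centroids and
    widths; (2) per-sample rule weights wₖ(t) = μₖ(t)/Σμ; (3) all rule
    consequents {b₀ᵏ, αᵏ} are solved jointly by ridge least squares so the
    defuzzified output matches the labels on the logit scale
    (z = logit(clip(y, 0.05, 0.95))).
    """
    if params is None:
        params = KSCParams()
    if isinstance(X, pd.DataFrame):
        if feature_ids is None:
            feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n, p = X.shape

    cluster = ksc_cluster(X, spec, params)
    sigma_row = compute_sigmas(params, p)
    rules = [
        FuzzyRule(centroid=c, sigma=sigma_row, intercept=0.0,
                  expansion_coeffs=np.zeros(n))
        for c in cluster.centroids
    ]
    model = KFISModel(
        rules=rules,
        kernel=spec,
        training_points=X.copy(),
        feature_ids=feature_ids or [],
        normalization_table=normalization_table,
        decision_threshold=decision_threshold,
        ksc_params=params,
        cluster=cluster,
    )

    R = model.n_rules
    w = _weights(_firing_matrix(model, X))  # n × R
    G = gram_matrix(spec, X)  # K(xᵢ, xₜ)
    base = np.hstack([np.ones((n, 1)), G])  # n × (1+m)
    design = np.hstack([w[:, [k]] * base for k in range(R)])  # n × R(1+m)

    z = logit(np.clip(y.astype(float), TARGET_CLIP, 1.0 - TARGET_CLIP))
    A = design.T @ design
    A[np.diag_indices_from(A)] += ridge if ridge > 0 else 0.0
    b = design.T @ z
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        logger.warning("singular normal equations; retrying with ridge 1e-6")
        A[np.diag_indices_from(A)] += 1e-6
        theta = np.linalg.solve(A, b)

    width = 1 + n
    for k, rule in enumerate(model.rules):
        block = theta[k * width : (k + 1) * width]
        rule.intercept = float(block[0])
        rule.expansion_coeffs = block[1:].copy()
    return model
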