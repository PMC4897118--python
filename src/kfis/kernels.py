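"""Mercer kernel evaluations and kernel-space distances.

Every other computational module measures similarity through one of four
kernels — linear, polynomial, radial basis function (RBF) and tan-sigmoid
(tansig) — so that clustering, memberships and rule consequents operate in
the (implicit) feature space of the kernel rather than on raw coordinates.
The feature map itself is never materialised: all quantities reduce to
kernel evaluations K(x, y), and squared feature-space distances come from
the polarisation identity

    d²_φ(x, y) = K(x, x) − 2 K(x, y) + K(y, y).

The tansig kernel is not positive semidefinite for all parameters, so the
squared distance above can come out (slightly) negative; it is clamped to
zero with a logged warning to keep downstream exponentials well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

KERNEL_NAMES = ("linear", "polynomial", "rbf", "tansig")

#: tolerance below which negative kernel squared distances are clamped silently
_NEG_TOL = 1e-9


class KernelConfigError(ValueError):
    """Invalid kernel name or parameters."""


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel with its parameters.

    Parameters
    ----------
    name
        One of ``linear``, ``polynomial``, ``rbf``, ``tansig``.
    gamma
        Scale parameter γ; must be positive for every kernel except
        ``linear`` (which ignores all parameters).
    coef
        Additive constant c ≥ 0 (polynomial, tansig).
    degree
        Polynomial degree d ≥ 1 (polynomial only).
    """

    name: str = "rbf"
    gamma: float = 0.5
    coef: float = 0.1
    degree: int = 3

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise KernelConfigError(
                f"unknown kernel {self.name!r}; choose one of {KERNEL_NAMES}"
            )
        if self.name == "linear":
            return  # linear ignores all parameters
        if not self.gamma > 0:
            raise KernelConfigError(f"{self.name} kernel requires gamma > 0")
        if self.name in ("polynomial", "tansig") and self.coef < 0:
            raise KernelConfigError(f"{self.name} kernel requires coef >= 0")
        if self.name == "polynomial":
            if int(self.degree) != self.degree or self.degree < 1:
                raise KernelConfigError("polynomial kernel requires integer degree >= 1")


def _pairwise(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """K(xᵢ, yⱼ) for all row pairs of two 2-D arrays."""
    if spec.name == "linear":
        return X @ Y.T
    if spec.name == "polynomial":
        return (spec.gamma * (X @ Y.T) + spec.coef) ** int(spec.degree)
    if spec.name == "rbf":
        return np.exp(-spec.gamma * cdist(X, Y, "sqeuclidean"))
    # tansig
    return np.tanh(spec.gamma * (X @ Y.T) + spec.coef)


def _as_vectors(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"dimension mismatch: {x.size} vs {y.size}")
    if x.size < 1:
        raise ValueError("vectors must have dimension >= 1")
    return x, y


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Evaluate K(x, y) for a single pair of equal-length vectors."""
    x, y = _as_vectors(x, y)
    return float(_pairwise(spec, x[None, :], y[None, :])[0, 0])


def kernel_sq_distance(spec: KernelSpec, x, y) -> float:
    """Squared feature-space distance K(x,x) − 2K(x,y) + K(y,y).

    Exactly 0 when ``x is y`` coincide; equals the squared Euclidean
    distance under the linear kernel.  Negative values (possible for the
    indefinite tansig kernel) are clamped to 0 with a warning.
    """
    x, y = _as_vectors(x, y)
    if np.array_equal(x, y):
        return 0.0
    d2 = (
        kernel_eval(spec, x, x)
        - 2.0 * kernel_eval(spec, x, y)
        + kernel_eval(spec, y, y)
    )
    if d2 < 0:
        if d2 < -_NEG_TOL:
            logger.warning(
                "negative kernel squared distance %.3e clamped to 0 (%s kernel)",
                d2,
                spec.name,
            )
        d2 = 0.0
    return d2


def gram_matrix(spec: KernelSpec, X) -> np.ndarray:
    """Exactly symmetric n×n matrix of pairwise kernel values over rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one data point")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in input matrix")
    G = _pairwise(spec, X, X)
    return (G + G.T) / 2.0


def sq_distance_matrix(spec: KernelSpec, G: np.ndarray) -> np.ndarray:
    """Pairwise kernel squared distances from a Gram matrix, clamped at 0."""
    diag = np.diag(G)
    D2 = diag[:, None] + diag[None, :] - 2.0 * G
    neg = D2.min()
    if neg < -_NEG_TOL:
        logger.warning(
            "negative kernel squared distances (min %.3e) clamped to 0", neg
        )
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return D2


def coordwise_sq_distance(spec: KernelSpec, x, c) -> np.ndarray:
    """Per-coordinate kernel squared distances between two vectors.

    For coordinate j this is K(xⱼ,xⱼ) − 2K(xⱼ,cⱼ) + K(cⱼ,cⱼ) with the
    kernel evaluated on scalars — the quantity inside the Gaussian
    membership of each fuzzy set.  Vectorised over coordinates; rows of a
    2-D ``x`` are handled at once.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    if x.shape[-1] != c.size:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} vs {c.size}")
    if spec.name == "linear":
        return (x - c) ** 2
    if spec.name == "rbf":
        return 2.0 - 2.0 * np.exp(-spec.gamma * (x - c) ** 2)
    if spec.name == "polynomial":
        g, co, d = spec.gamma, spec.coef, int(spec.degree)
        d2 = (
            (g * x * x + co) ** d
            - 2.0 * (g * x * c + co) ** d
            + (g * c * c + co) ** d
        )
    else:  # tansig
        g, co = spec.gamma, spec.coef
        d2 = (
            np.tanh(g * x * x + co)
            - 2.0 * np.tanh(g * x * c + co)
            + np.tanh(g * c * c + co)
        )
    neg = d2.min()
    if neg < -_NEG_TOL:
        logger.warning(
            "negative per-coordinate kernel distances (min %.3e) clamped to 0", neg
        )
    return np.maximum(d2, 0.0)
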