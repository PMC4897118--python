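"""Independent brute-force reference implementations used only by tests.

Everything here works directly on raw coordinates with explicit loops and
textbook formulas — no imports from the package's computational modules —
so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def classic_subtractive_clustering(
    X: np.ndarray,
    ra: float,
    eta: float = 1.25,
    accept: float = 0.75,
    reject: float = 0.15,
):
    """Chiu-style subtractive clustering on raw Euclidean coordinates.

    Returns (centroid index list, final potential vector).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    alpha = 4.0 / ra**2
    rb = eta * ra
    beta = 4.0 / rb**2
    D2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D2[i, j] = np.sum((X[i] - X[j]) ** 2)
    p = np.array([np.exp(-alpha * D2[i]).sum() for i in range(n)])

    def revise(p, winner, p_star):
        out = p - p_star * np.exp(-beta * D2[:, winner])
        out = np.maximum(out, 0.0)
        out[winner] = 0.0
        return out

    first = int(np.argmax(p))
    p1 = p[first]
    accepted = [first]
    p = revise(p, first, p1)
    while True:
        cand = int(np.argmax(p))
        p_star = p[cand]
        if p_star <= 0:
            break
        if p_star > accept * p1:
            ok = True
        elif p_star < reject * p1:
            break
        else:
            dmin = min(math.sqrt(D2[cand, a]) for a in accepted)
            ok = dmin / ra + p_star / p1 >= 1.0
        if ok:
            accepted.append(cand)
            p = revise(p, cand, p_star)
        else:
            p[cand] = 0.0
    return accepted, p


def classic_tsk_fit_predict(
    X_train: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray,
    ra: float,
    eta: float = 1.25,
    accept: float = 0.75,
    reject: float = 0.15,
    ridge: float = 1e-6,
    clip: float = 0.05,
):
    """Non-kernel TSK classifier: subtractive clustering + Gaussian
    memberships on raw coordinates + dot-product consequent expansions,
    solved by the same ridge least squares on logit targets.

    Returns predicted probabilities on ``X_test``.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    n, p = X_train.shape
    idx, _ = classic_subtractive_clustering(X_train, ra, eta, accept, reject)
    centroids = X_train[idx]
    sigma = ra / math.sqrt(8.0)

    def mu_matrix(Xq):
        mu = np.zeros((Xq.shape[0], len(idx)))
        for t in range(Xq.shape[0]):
            for k, c in enumerate(centroids):
                a = np.exp(-((Xq[t] - c) ** 2) / (2 * sigma**2))
                mu[t, k] = np.prod(a)
        return mu

    mu = mu_matrix(X_train)
    w = mu / mu.sum(axis=1, keepdims=True)
    G = X_train @ X_train.T  # plain dot products
    base = np.hstack([np.ones((n, 1)), G])
    design = np.hstack([w[:, [k]] * base for k in range(len(idx))])
    yy = np.clip(np.asarray(y, dtype=float), clip, 1 - clip)
    z = np.log(yy / (1 - yy))
    A = design.T @ design + ridge * np.eye(design.shape[1])
    theta = np.linalg.solve(A, design.T @ z)

    mu_q = mu_matrix(X_test)
    w_q = mu_q / mu_q.sum(axis=1, keepdims=True)
    Kq = X_test @ X_train.T
    base_q = np.hstack([np.ones((X_test.shape[0], 1)), Kq])
    width = 1 + n
    Y = np.zeros(X_test.shape[0])
    for k in range(len(idx)):
        block = theta[k * width : (k + 1) * width]
        Y += w_q[:, k] * (base_q @ block)
    return 1.0 / (1.0 + np.exp(-Y)), idx


def concordance_auc(scores, y_true) -> float:
    """AUC as the Mann–Whitney pairwise concordance probability.

    Ties in scores between a positive and a negative count half.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def pooled_t_and_p(a, b):
    """Textbook pooled two-sample t statistic and two-sided P value."""
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
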