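"""Classifier evaluation: confusion metrics, ROC/AUC, interleaved k-fold
cross-validation and per-fold hyperparameter selection.

The positive class is label 1 (the minority/AML-like class).  The
cross-validation plan is *interleaved*: 1-based sample i goes to fold
((i − 1) mod F) + 1, so fold 1 holds samples 1, F+1, 2F+1, …  Held-out
predictions from all folds are pooled into one confusion matrix over the
full sample set.  Feature ranking, selection and normalization are redone
inside each training fold by default; ``paper_order=True`` performs them
once on the full data before splitting (the leakage-prone but historically
common ordering).

Model selection picks, per fold, the (cluster radius, kernel γ) grid point
with the best validation accuracy (ties to the smaller radius, then the
smaller γ) and returns the per-parameter lower median of the fold winners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .inference import fit as kfis_fit
from .inference import predict as kfis_predict
from .inference import predict_proba as kfis_predict_proba
from .kernels import KernelSpec
from .ksc import KSCParams
from .preprocess import apply_normalization, minmax_normalize, select_features, t_test_rank

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with class 1 positive: layout (TN, FP; FN, TP)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    specificity: float
    f_measure: float
    accuracy: float
    zero_denominator: list[str] = field(default_factory=list)
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Standard two-class counts; labels must lie in {0, 1}."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} contains labels outside {{0,1}}: {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, specificity, F-measure and accuracy from counts.

    A metric whose denominator is zero is reported as 0 and named in
    ``zero_denominator`` rather than returned as NaN.
    """
    flags: list[str] = []
    precision = _safe_div(cm.tp, cm.fp + cm.tp, "precision", flags)
    recall = _safe_div(cm.tp, cm.fn + cm.tp, "recall", flags)
    specificity = _safe_div(cm.tn, cm.fp + cm.tn, "specificity", flags)
    f_measure = _safe_div(2 * precision * recall, precision + recall, "f_measure", flags)
    accuracy = _safe_div(cm.tp + cm.tn, cm.total, "accuracy", flags)
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        f_measure=f_measure,
        accuracy=accuracy,
        zero_denominator=flags,
    )


def roc_curve(scores, y_true) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) sweeping the score threshold, plus trapezoid AUC.

    Tied scores move together between points.  Raises on single-class truth
    (the curve is undefined).
    """
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC/AUC undefined for single-class y_true")
    fpr, tpr, _ = skmetrics.roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass(frozen=True)
class CVPlan:
    """Deterministic interleaved fold assignment (0-based folds)."""

    n_samples: int
    n_folds: int
    assignment: np.ndarray  # fold index per sample

    def fold_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == f)


def interleaved_cv_plan(n: int, F: int = 10) -> CVPlan:
    """Fold f (1-based) holds the samples whose 1-based index ≡ f (mod F)."""
    if F > n:
        raise ValueError(f"more folds ({F}) than samples ({n})")
    if F < 1:
        raise ValueError("need at least one fold")
    return CVPlan(n_samples=n, n_folds=F, assignment=np.arange(n) % F)


@dataclass
class CVResult:
    pooled: ConfusionMatrix
    fold_train_accuracy: list[float]
    fold_test_accuracy: list[float]
    scores: np.ndarray  # pooled held-out ŷ per sample (NaN if skipped)
    predictions: np.ndarray  # pooled held-out labels per sample (-1 if skipped)


def cross_validate(
    X: pd.DataFrame,
    y,
    spec: KernelSpec,
    params: KSCParams,
    plan: CVPlan,
    k_features: int,
    paper_order: bool = False,
    ridge: float = 1e-6,
    decision_threshold: float = 0.5,
) -> CVResult:
    """Pool held-out K-FIS predictions over every fold of the plan.

    Per fold: rank genes by t-test and fit the min–max table on the
    training rows only (unless ``paper_order``), select the top
    ``k_features`` genes, fit, and score the held-out rows.
    """
    y = np.asarray(y).ravel()
    n = X.shape[0]
    if plan.n_samples != n:
        raise ValueError("plan does not cover this sample count")
    scores = np.full(n, np.nan)
    preds = np.full(n, -1, dtype=int)
    train_acc: list[float] = []
    test_acc: list[float] = []

    if paper_order:
        ranking_all = t_test_rank(X, y)
        genes_all = select_features(ranking_all, k_features)
        Xn_all, _ = minmax_normalize(X)

    for f in range(plan.n_folds):
        test_idx = plan.fold_indices(f)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            logger.warning("fold %d skipped: training rows lack both classes", f + 1)
            continue
        if paper_order:
            Xtr = Xn_all.iloc[train_idx][genes_all]
            Xte = Xn_all.iloc[test_idx][genes_all]
        else:
            ranking = t_test_rank(X.iloc[train_idx], y_tr)
            genes = select_features(ranking, k_features)
            Xtr_raw = X.iloc[train_idx][genes]
            Xn, table = minmax_normalize(Xtr_raw)
            Xtr = Xn
            Xte = apply_normalization(X.iloc[test_idx][genes], table)
        model = kfis_fit(
            Xtr, y_tr, spec, params, ridge=ridge,
            decision_threshold=decision_threshold,
        )
        scores[test_idx] = kfis_predict_proba(model, Xte.to_numpy(dtype=float))
        preds[test_idx] = (scores[test_idx] >= decision_threshold).astype(int)
        train_acc.append(
            float((kfis_predict(model, Xtr.to_numpy(dtype=float)) == y_tr).mean())
        )
        test_acc.append(float((preds[test_idx] == y[test_idx]).mean()))

    done = preds >= 0
    pooled = confusion(y[done], preds[done])
    return CVResult(
        pooled=pooled,
        fold_train_accuracy=train_acc,
        fold_test_accuracy=test_acc,
        scores=scores,
        predictions=preds,
    )


def _lower_median(values: list[float]) -> float:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def model_select(
    X: pd.DataFrame,
    y,
    spec: KernelSpec,
    r_a_grid,
    gamma_grid,
    plan: CVPlan,
    k_features: int,
    params_template: KSCParams | None = None,
    ridge: float = 1e-6,
) -> tuple[float, float, pd.DataFrame]:
    """Per-fold grid search over (cluster radius, γ), combined by medians.

    Returns (chosen r_a, chosen γ, per-fold report).  Each fold's winner is
    the grid point with maximal validation accuracy, ties resolved toward
    the smaller radius and then the smaller γ; the final values are the
    per-parameter lower medians of the fold winners.
    """
    if params_template is None:
        params_template = KSCParams()
    r_a_grid = list(r_a_grid)
    gamma_grid = list(gamma_grid) if gamma_grid is not None else [spec.gamma]
    if not r_a_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    y = np.asarray(y).ravel()
    n = X.shape[0]
    rows = []
    winners: list[tuple[float, float]] = []

    for f in range(plan.n_folds):
        val_idx = plan.fold_indices(f)
        learn_idx = np.setdiff1d(np.arange(n), val_idx)
        y_learn = y[learn_idx]
        if len(np.unique(y_learn)) < 2 or len(np.unique(y[val_idx])) < 1:
            logger.warning("fold %d omitted from model selection", f + 1)
            continue
        ranking = t_test_rank(X.iloc[learn_idx], y_learn)
        genes = select_features(ranking, k_features)
        Xl, table = minmax_normalize(X.iloc[learn_idx][genes])
        Xv = apply_normalization(X.iloc[val_idx][genes], table)
        best = None
        for ra in sorted(r_a_grid):
            params = KSCParams(
                cluster_radius=ra,
                squash_factor=params_template.squash_factor,
                accept_ratio=params_template.accept_ratio,
                reject_ratio=params_template.reject_ratio,
            )
            for gamma in sorted(gamma_grid):
                kspec = KernelSpec(spec.name, gamma=gamma, coef=spec.coef,
                                   degree=spec.degree)
                try:
                    model = kfis_fit(Xl, y_learn, kspec, params, ridge=ridge)
                    acc = float(
                        (kfis_predict(model, Xv.to_numpy(dtype=float)) == y[val_idx]).mean()
                    )
                except Exception as err:  # noqa: BLE001 — a grid point may fail
                    logger.warning("fold %d (ra=%g, gamma=%g) failed: %s",
                                   f + 1, ra, gamma, err)
                    continue
                rows.append({"fold": f + 1, "r_a": ra, "gamma": gamma,
                             "val_accuracy": acc})
                if best is None or acc > best[0]:
                    best = (acc, ra, gamma)
        if best is not None:
            winners.append((best[1], best[2]))

    if not winners:
        raise RuntimeError("model selection failed in every fold")
    chosen_ra = _lower_median([w[0] for w in winners])
    chosen_gamma = _lower_median([w[1] for w in winners])
    return chosen_ra, chosen_gamma, pd.DataFrame(rows)
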