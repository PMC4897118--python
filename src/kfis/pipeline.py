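"""End-to-end run orchestration: impute → normalize → CV → report.

`run_pipeline` is what the ``kfis run`` subcommand executes: it loads (or
expects) an expression matrix plus labels, cross-validates a K-FIS
configuration over a list of feature counts, and writes a metrics table,
per-feature-count ROC points, a model trained on the full data at the
best-performing feature count, and a log of the effective configuration.
Everything is deterministic for a fixed config; partial outputs are
removed if any stage fails.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import io as kio
from .evaluation import cross_validate, interleaved_cv_plan, metrics, roc_curve
from .inference import fit as kfis_fit
from .kernels import KernelSpec
from .ksc import KSCParams
from .preprocess import impute_missing, minmax_normalize, select_features, t_test_rank

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    matrix_path: str
    labels_path: str
    output_dir: str
    kernel: KernelSpec = field(default_factory=KernelSpec)
    ksc: KSCParams = field(default_factory=KSCParams)
    folds: int = 10
    feature_counts: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    paper_order: bool = False
    decision_threshold: float = 0.5
    ridge: float = 1e-6
    transpose: bool = False

    def __post_init__(self) -> None:
        if list(self.feature_counts) != sorted(set(self.feature_counts)):
            raise ValueError("feature_counts must be strictly increasing")


class StageError(RuntimeError):
    """An error annotated with the pipeline stage that raised it."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:
        raise StageError(f"stage {name!r} failed: {err}") from err


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full classification pipeline; returns the metrics table."""
    os.makedirs(config.output_dir, exist_ok=True)
    written: list[str] = []
    try:
        X = _stage("read", kio.read_expression, config.matrix_path,
                   transpose=config.transpose)
        y = _stage("read", kio.read_labels, config.labels_path)
        y = y.reindex(X.index)
        if y.isna().any():
            raise StageError("stage 'read' failed: labels missing for some samples")
        X = _stage("impute", impute_missing, X)

        logger.info("config: %s", dataclasses.asdict(config))
        plan = interleaved_cv_plan(X.shape[0], config.folds)
        rows = []
        for k in config.feature_counts:
            result = _stage(
                "cv", cross_validate, X, y.to_numpy(), config.kernel, config.ksc,
                plan, k, paper_order=config.paper_order, ridge=config.ridge,
                decision_threshold=config.decision_threshold,
            )
            rep = metrics(result.pooled)
            done = result.predictions >= 0
            points, auc = roc_curve(result.scores[done], y.to_numpy()[done])
            roc_path = os.path.join(config.output_dir, f"roc_F{k}.tsv")
            pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
                roc_path, sep="\t", index=False
            )
            written.append(roc_path)
            rows.append(
                {
                    "model": f"F{k}",
                    "k_features": k,
                    "accuracy": rep.accuracy,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "specificity": rep.specificity,
                    "f_measure": rep.f_measure,
                    "auc": auc,
                }
            )
            logger.info("F%d: pooled accuracy %.4f (auc %.4f)", k, rep.accuracy, auc)
        table = pd.DataFrame(rows)

        metrics_path = os.path.join(config.output_dir, "metrics.tsv")
        table.to_csv(metrics_path, sep="\t", index=False, float_format="%.6f")
        written.append(metrics_path)

        # final model on all samples at the best-performing feature count
        best_k = int(table.loc[table["accuracy"].idxmax(), "k_features"])
        ranking = _stage("select", t_test_rank, X, y.to_numpy())
        genes = select_features(ranking, best_k)
        Xn, norm_table = _stage("normalize", minmax_normalize, X[genes])
        model = _stage(
            "fit", kfis_fit, Xn, y.to_numpy(), config.kernel, config.ksc,
            ridge=config.ridge, feature_ids=genes, normalization_table=norm_table,
            decision_threshold=config.decision_threshold,
        )
        model_path = os.path.join(config.output_dir, "model.json")
        kio.save_model(model, model_path)
        written.append(model_path)
        return table
    except Exception:
        for path in written:  # do not leave half-written artifacts behind
            try:
                os.unlink(path)
            except OSError:
                pass
        raise
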