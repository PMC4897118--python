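"""Delimited-text readers/writers and JSON model serialization.

Expression files are samples-in-rows delimited text: first row gene ids,
first column sample ids, cells numeric or missing (empty field or ``NA``).
Label files are two columns (sample id, class in {0, 1}).  A fitted model
is stored as one self-describing JSON document with a mandatory format
version; loading a tampered or truncated file fails loudly.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .inference import FuzzyRule, KFISModel
from .kernels import KernelSpec
from .ksc import KSCParams
from .preprocess import DataError

MODEL_FORMAT_VERSION = 1

NA_VALUES = ["", "NA"]


class FormatError(ValueError):
    """Unreadable or incompatible file format."""


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","


def read_expression(path, sep: str | None = None, transpose: bool = False) -> pd.DataFrame:
    """Read a samples × genes matrix; ``transpose`` for genes-in-rows files."""
    use_sep = _sep_for(path, sep)
    # pandas silently renames duplicate header fields, so check them raw
    header = pd.read_csv(path, sep=use_sep, header=None, nrows=1).iloc[0, 1:]
    if header.duplicated().any():
        dupes = header[header.duplicated()].unique().tolist()
        raise DataError(f"duplicate header ids in {path}: {dupes}")
    frame = pd.read_csv(
        path, sep=use_sep, index_col=0,
        na_values=NA_VALUES, keep_default_na=False,
    )
    if transpose:
        frame = frame.T
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids in {path}: {dupes}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids in {path}: {dupes}")
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as err:
            raise DataError(f"non-numeric cell in gene column {col!r} of {path}: {err}")
    return frame


def write_expression(frame: pd.DataFrame, path, sep: str | None = None) -> None:
    frame.to_csv(path, sep=_sep_for(path, sep), na_rep="NA")


def read_labels(path, sep: str | None = None) -> pd.Series:
    """Two-column file (sample id, class in {0,1}) -> integer series."""
    frame = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if frame.shape[1] != 1:
        raise DataError(f"label file {path} must have exactly two columns")
    labels = frame.iloc[:, 0]
    bad = set(labels.unique()) - {0, 1}
    if bad:
        raise DataError(f"labels outside {{0,1}} in {path}: {sorted(bad)}")
    return labels.astype(int).rename("label")


def write_labels(labels: pd.Series, path, sep: str | None = None) -> None:
    labels.rename("label").to_csv(path, sep=_sep_for(path, sep), index_label="sample")


def write_ranking(ranking, path, sep: str = "\t") -> None:
    """Export a t-test ranking as (gene id, t, p, rank) delimited text."""
    out = ranking.table[["t_stat", "p_value", "rank"]].sort_values("rank")
    out.to_csv(path, sep=sep, index_label="gene")


def save_model(model: KFISModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "kernel": {
            "name": model.kernel.name,
            "gamma": model.kernel.gamma,
            "coef": model.kernel.coef,
            "degree": model.kernel.degree,
        },
        "ksc_params": {
            "cluster_radius": model.ksc_params.cluster_radius,
            "squash_factor": model.ksc_params.squash_factor,
            "accept_ratio": model.ksc_params.accept_ratio,
            "reject_ratio": model.ksc_params.reject_ratio,
        },
        "decision_threshold": model.decision_threshold,
        "feature_ids": list(model.feature_ids),
        "normalization_table": (
            None
            if model.normalization_table is None
            else {
                str(g): [float(r["min"]), float(r["max"])]
                for g, r in model.normalization_table.iterrows()
            }
        ),
        "training_points": model.training_points.tolist(),
        "rules": [
            {
                "centroid": r.centroid.tolist(),
                "sigma": r.sigma.tolist(),
                "intercept": r.intercept,
                "expansion_coeffs": r.expansion_coeffs.tolist(),
            }
            for r in model.rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> KFISModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as err:
        raise FormatError(f"model file {path} is corrupt or truncated: {err}")
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"model file {path} has format version {version!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    table = doc["normalization_table"]
    norm = (
        None
        if table is None
        else pd.DataFrame(
            {"min": {g: mm[0] for g, mm in table.items()},
             "max": {g: mm[1] for g, mm in table.items()}}
        )
    )
    return KFISModel(
        rules=[
            FuzzyRule(
                centroid=np.asarray(r["centroid"]),
                sigma=np.asarray(r["sigma"]),
                intercept=float(r["intercept"]),
                expansion_coeffs=np.asarray(r["expansion_coeffs"]),
            )
            for r in doc["rules"]
        ],
        kernel=KernelSpec(**doc["kernel"]),
        training_points=np.asarray(doc["training_points"], dtype=float),
        feature_ids=list(doc["feature_ids"]),
        normalization_table=norm,
        decision_threshold=float(doc["decision_threshold"]),
        ksc_params=KSCParams(**doc["ksc_params"]),
    )
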