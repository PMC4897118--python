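"""Expression-matrix preprocessing and t-test feature ranking.

The working container is a pandas ``DataFrame`` with samples in rows and
genes in columns (gene identifiers as column labels, sample identifiers as
the index); missing entries are ``NaN``.  The steps mirror the standard
microarray front end for a two-class problem:

1. mean imputation per gene,
2. per-gene min–max normalization to [0, 1] (constant genes map to 0.5),
3. pooled-variance two-sample t-test per gene, ranking genes by ascending
   P value (ties by larger \\|t\\|, then gene id),
4. nested forward selection of the top-k genes.

The normalization statistics are returned as a table so that held-out data
can be mapped with the *training* min/max (values may then fall outside
[0, 1]; they are deliberately not clipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DataError(ValueError):
    """Malformed or degenerate input data."""


def _check_frame(m: pd.DataFrame) -> None:
    if m.columns.has_duplicates:
        dupes = m.columns[m.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids: {dupes}")
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids: {dupes}")


def impute_missing(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing entry by the mean of its gene's observed values."""
    _check_frame(m)
    all_missing = m.columns[m.isna().all(axis=0)]
    if len(all_missing):
        raise DataError(f"gene(s) with all entries missing: {list(all_missing)}")
    return m.fillna(m.mean(axis=0))


def minmax_normalize(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene min–max rescaling to [0, 1].

    Returns the normalized matrix and a table with columns ``min`` and
    ``max`` (one row per gene) for reuse on held-out data.  Genes whose
    max equals their min are mapped to the constant 0.5.
    """
    _check_frame(m)
    if m.isna().any().any():
        raise DataError("missing entries present; impute before normalizing")
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    table = pd.DataFrame({"min": lo, "max": hi})
    return apply_normalization(m, table), table


def apply_normalization(m: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a previously computed (min, max) table; no clipping of extremes."""
    missing = m.columns.difference(table.index)
    if len(missing):
        raise DataError(f"gene(s) absent from normalization table: {list(missing)}")
    lo = table["min"].reindex(m.columns)
    hi = table["max"].reindex(m.columns)
    span = hi - lo
    degenerate = span == 0
    safe_span = span.mask(degenerate, 1.0)
    out = (m - lo) / safe_span
    out.loc[:, degenerate[degenerate].index] = 0.5
    return out


@dataclass
class TTestRanking:
    """Per-gene pooled-variance t statistics, P values and ranks.

    ``table`` is indexed by gene id with columns ``t_stat``, ``p_value``,
    ``pooled_sd``, ``mean_0``, ``mean_1`` and ``rank`` (1-based; rank 1 is
    the smallest P value).  ``n1``/``n2`` are the class sample counts
    (labels 0 and 1 respectively).
    """

    table: pd.DataFrame
    n1: int
    n2: int

    def __len__(self) -> int:
        return len(self.table)


def t_test_rank(m: pd.DataFrame, y) -> TTestRanking:
    """Rank genes by a pooled-variance two-sample t-test.

    The statistic is (mean₀ − mean₁) / (s_pooled · √(1/n₁ + 1/n₂)) with the
    pooled variance weighting each class's unbiased variance by n−1; the
    two-sided P value uses n₁+n₂−2 degrees of freedom.  Genes with zero
    pooled variance get t = ±inf, p = 0 when the class means differ and
    t = 0, p = 1 when they coincide.
    """
    y = np.asarray(y).ravel()
    if len(y) != m.shape[0]:
        raise DataError("label vector length does not match sample count")
    if m.isna().any().any():
        raise DataError("missing entries present; impute before testing")
    mask0 = y == 0
    mask1 = y == 1
    n1, n2 = int(mask0.sum()), int(mask1.sum())
    if n1 < 2 or n2 < 2:
        raise DataError("both classes need at least 2 samples")

    X = m.to_numpy(dtype=float)
    g0, g1 = X[mask0], X[mask1]
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    v0, v1 = g0.var(axis=0, ddof=1), g1.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    pooled_sd = np.sqrt(((n1 - 1) * v0 + (n2 - 1) * v1) / df)
    se = pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2)

    diff = m0 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_sd = pooled_sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_sd & (diff != 0), np.sign(diff) * np.inf, t)
    t = np.where(zero_sd & (diff == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero_sd & (diff == 0), 1.0, p)

    table = pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "pooled_sd": pooled_sd,
            "mean_0": m0,
            "mean_1": m1,
        },
        index=m.columns,
    )
    # rank: ascending p, ties by larger |t|, then lexicographic gene id
    order = table.assign(_abs_t=np.abs(table["t_stat"]), _gid=table.index.astype(str))
    order = order.sort_values(
        ["p_value", "_abs_t", "_gid"], ascending=[True, False, True], kind="mergesort"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["rank"] = ranks.reindex(table.index)
    return TTestRanking(table=table, n1=n1, n2=n2)


def select_features(r: TTestRanking, k: int) -> list:
    """Top-k gene ids in rank order; nested — k₁ ≤ k₂ gives a prefix."""
    if k <= 0 or k > len(r):
        raise ValueError(f"k must be in 1..{len(r)}, got {k}")
    ordered = r.table.sort_values("rank").index
    return list(ordered[:k])


def pvalue_cdf(r: TTestRanking) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of the P values: (sorted unique p, fraction ≤ p)."""
    p = np.sort(r.table["p_value"].to_numpy())
    uniq, counts = np.unique(p, return_counts=True)
    frac = np.cumsum(counts) / p.size
    return uniq, frac
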