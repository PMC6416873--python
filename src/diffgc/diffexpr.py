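"""Two-group differential expression statistics and gene-list selection.

The workhorse is the classical Student two-sample t-test with pooled
variance (df = n1 + n2 - 2), applied gene-wise on the analysis scale, plus
an orientation-free linear-scale fold difference (max/min ratio of group
means). Selection applies raw thresholds (no multiple-testing correction,
matching the classical microarray convention); a Benjamini-Hochberg column
is emitted for information only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def pooled_ttest(a: np.ndarray, b: np.ndarray, welch: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized row-wise two-sample t-test.

    ``a`` and ``b`` are (genes x n1) and (genes x n2). Returns (t, p) with
    two-sided p-values; rows with zero pooled variance get t=0, p=1.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    degenerate = se2 == 0
    if degenerate.any():
        log.debug("%d zero-variance genes set to t=0, p=1", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, se2)
    t = np.where(degenerate, 0.0, (m1 - m2) / np.sqrt(safe))
    p = np.where(degenerate, 1.0, 2 * sps.t.sf(np.abs(t), df))
    return t, p


def _split(matrix: ExpressionMatrix, groups: pd.Series | dict
           ) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    groups = pd.Series(groups)
    groups = groups.reindex(matrix.samples)
    if groups.isna().any():
        raise ValidationError("group labels missing for some samples")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {levels}")
    values = matrix.data.to_numpy(dtype=float)
    mask1 = (groups == levels[0]).to_numpy()
    return values[:, mask1], values[:, ~mask1], levels, values


def two_sample_ttest(matrix: ExpressionMatrix, groups: pd.Series | dict,
                     welch: bool = False) -> pd.DataFrame:
    """Gene-wise t-test between the two groups in ``groups``.

    Groups are ordered by sorted label; positive t means higher mean in the
    first group. Returns a DataFrame indexed by gene with columns
    ``mean_group1``, ``mean_group2``, ``t``, ``p_value``, ``p_adj_bh``,
    ``direction``.
    """
    a, b, levels, _ = _split(matrix, groups)
    t, p = pooled_ttest(a, b, welch=welch)
    out = pd.DataFrame({
        "mean_group1": a.mean(axis=1),
        "mean_group2": b.mean(axis=1),
        "t": t,
        "p_value": p,
        "p_adj_bh": multipletests(p, method="fdr_bh")[1],
        "direction": np.where(t >= 0, f"up_in_{levels[0]}", f"up_in_{levels[1]}"),
    }, index=matrix.genes)
    out.index.name = "gene_id"
    return out


def fold_change(matrix: ExpressionMatrix, groups: pd.Series | dict,
                input_scale: str | None = None,
                pseudo: float = 1e-9) -> pd.Series:
    """Orientation-free fold difference max(m1,m2)/min(m1,m2) of the
    linear-scale group means.

    If the input is on the log2 scale the means are exponentiated before the
    ratio. Genes with both group means zero get fold 1 (logged).
    """
    a, b, _, _ = _split(matrix, groups)
    scale = input_scale or matrix.scale
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    if scale in ("log2", "standardized", "pooled"):
        m1, m2 = np.exp2(m1), np.exp2(m2)
    both_zero = (m1 == 0) & (m2 == 0)
    if both_zero.any():
        log.debug("%d genes with both group means zero get fold 1",
                  int(both_zero.sum()))
    hi = np.maximum(m1, m2) + pseudo
    lo = np.minimum(m1, m2) + pseudo
    fold = np.where(both_zero, 1.0, hi / lo)
    return pd.Series(fold, index=matrix.genes, name="fold_difference")


def differential_expression(matrix: ExpressionMatrix, groups: pd.Series | dict,
                            welch: bool = False) -> pd.DataFrame:
    """t-test table joined with the fold-difference column."""
    stats = two_sample_ttest(matrix, groups, welch=welch)
    stats["fold_difference"] = fold_change(matrix, groups)
    return stats


def select_genes(stats: pd.DataFrame, p_threshold: float = 0.05,
                 fc_threshold: float | None = None) -> list[str]:
    """Genes passing the raw thresholds, ordered by ascending p-value,
    ties broken by descending |t| then gene ID."""
    if stats.empty:
        raise ValidationError("empty statistics table")
    keep = stats["p_value"] < p_threshold
    if fc_threshold is not None:
        keep &= stats["fold_difference"] >= fc_threshold
    selected = stats.loc[keep]
    order = sorted(selected.index,
                   key=lambda g: (selected.at[g, "p_value"],
                                  -abs(selected.at[g, "t"]), str(g)))
    return list(order)
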