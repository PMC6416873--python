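"""Expression normalization chains.

Two chains are provided:

* the RNA-seq chain applied to raw counts of a single dataset:
  CPM -> quantile normalization -> log2(x + pseudocount) -> iterated
  median-centering across genes and samples;
* the cross-dataset integration chain: per-gene z-standardization within
  each dataset, pooling over the shared gene universe, and a final quantile
  normalization of the pooled matrix.

Module-level functions operate on :class:`~diffgc.containers.ExpressionMatrix`
(genes x samples); :class:`QuantileNormalizer` and :class:`GeneStandardizer`
are scikit-learn transformers on samples-as-rows arrays whose fitted state
(reference distribution, per-gene means/sds) can be frozen on a training
cohort and applied to external samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# numpy cores (columns are the units being normalized)

def _cpm_core(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("all-zero sample column: CPM undefined")
    return counts / totals * 1e6


def _quantile_core(values: np.ndarray) -> np.ndarray:
    """Force every column to the mean of the column order statistics.

    Tied values receive the mean of the reference values at their tied
    ranks (average ranks interpolated on the reference distribution).
    """
    if np.isnan(values).any():
        raise ValidationError("missing values: quantile normalization undefined")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def _median_center_core(values: np.ndarray, tol: float = 1e-6,
                        max_iter: int = 10) -> np.ndarray:
    out = values.astype(float).copy()
    for _ in range(max_iter):
        row_med = np.median(out, axis=1, keepdims=True)
        out -= row_med
        col_med = np.median(out, axis=0, keepdims=True)
        out -= col_med
        if (np.abs(np.median(out, axis=1)).max() <= tol
                and np.abs(np.median(out, axis=0)).max() <= tol):
            break
    else:
        log.warning("median centering hit the iteration cap (%d)", max_iter)
    return out


def _zscore_rows_core(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row standardization (ddof=1). Returns (standardized, constant_mask)."""
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] == 0)
    safe = np.where(sds == 0, 1.0, sds)
    out = (values - means) / safe
    out[constant, :] = 0.0
    return out, constant


# ---------------------------------------------------------------------------
# ExpressionMatrix operations

def cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: each sample column rescaled to sum to 1e6."""
    if counts.scale != "counts":
        raise ValidationError(f"cpm expects counts scale, got {counts.scale!r}")
    return counts.with_values(_cpm_core(counts.data.to_numpy(dtype=float)), scale="cpm")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples; preserves within-column ranks."""
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    return matrix.with_values(_quantile_core(matrix.data.to_numpy(dtype=float)),
                              scale=matrix.scale)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); monotone, defined for x >= 0."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    values = matrix.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("log2 transform requires nonnegative values")
    return matrix.with_values(np.log2(values + pseudocount), scale="log2")


def median_center(matrix: ExpressionMatrix, tol: float = 1e-6,
                  max_iter: int = 10) -> ExpressionMatrix:
    """Iterated gene-then-sample median subtraction until both sets of
    medians are within ``tol`` of zero (or the iteration cap)."""
    return matrix.with_values(
        _median_center_core(matrix.data.to_numpy(dtype=float), tol, max_iter),
        scale=matrix.scale)


def zscore_within_dataset(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization to mean 0, sd 1 (sample sd, ddof=1).

    Constant gene rows are set to zero and logged rather than producing
    non-finite values.
    """
    out, constant = _zscore_rows_core(matrix.data.to_numpy(dtype=float))
    if constant.any():
        log.warning("%d constant gene rows set to zero during standardization",
                    int(constant.sum()))
    return matrix.with_values(out, scale="standardized")


def pool_datasets(datasets: list[ExpressionMatrix],
                  cohort_ids: list[str] | None = None) -> ExpressionMatrix:
    """Pool standardized datasets over their shared gene set and
    quantile-normalize the pooled matrix.

    Sample IDs are prefixed with the cohort ID to guarantee uniqueness;
    genes are restricted to the (sorted) intersection of gene sets.
    """
    if len(datasets) < 2:
        raise ValidationError("pooling needs >= 2 datasets")
    if cohort_ids is None:
        cohort_ids = [f"ds{i + 1}" for i in range(len(datasets))]
    shared: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        shared &= set(ds.genes)
    if not shared:
        raise ValidationError("empty gene intersection across datasets")
    genes = sorted(shared)
    frames = []
    for cid, ds in zip(cohort_ids, datasets):
        frame = ds.data.loc[genes]
        frame = frame.rename(columns={c: f"{cid}:{c}" for c in frame.columns})
        frames.append(frame)
    pooled = pd.concat(frames, axis=1)
    values = _quantile_core(pooled.to_numpy(dtype=float))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=pooled.columns),
                            scale="pooled")


def normalize_rnaseq(counts: ExpressionMatrix, pseudocount: float = 1.0,
                     log2_first: bool = False) -> ExpressionMatrix:
    """Full RNA-seq chain: CPM -> quantile -> log2 -> median-center.

    ``log2_first=True`` swaps the quantile and log2 stages for sensitivity
    analysis; the default order is the literal chain.
    """
    out = cpm(counts)
    if log2_first:
        out = log2_transform(out, pseudocount)
        out = quantile_normalize(out)
    else:
        out = quantile_normalize(out)
        out = log2_transform(out, pseudocount)
    return median_center(out)


# ---------------------------------------------------------------------------
# scikit-learn transformers (samples as rows)

class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Map each sample to a reference distribution learned at fit time.

    The reference is the across-sample mean of per-sample order statistics;
    ``transform`` replaces each sample's values by the reference quantiles at
    their (average) ranks, so previously unseen samples are normalized
    against the training distribution.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        positions = np.arange(1, self.n_features_in_ + 1, dtype=float)
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            ranks = rankdata(X[i], method="average")
            out[i] = np.interp(ranks, positions, self.reference_)
        return out


class GeneStandardizer(TransformerMixin, BaseEstimator):
    """Per-gene z-standardization with frozen training means and sds.

    Uses the sample standard deviation (ddof=1). Genes constant in the
    training data transform to zero.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.constant_mask_ = sds == 0
        self.sds_ = np.where(self.constant_mask_, 1.0, sds)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X)
        out = (X - self.means_) / self.sds_
        out[:, self.constant_mask_] = 0.0
        return out
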