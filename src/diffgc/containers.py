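"""Core in-memory containers for expression and mutation data.

Expression matrices follow the field convention of genes as rows and
samples as columns, carried in a :class:`pandas.DataFrame` together with a
``scale`` tag that records where the matrix sits in the normalization
chain (``counts`` -> ``cpm`` -> ``log2`` / ``standardized`` -> ``pooled``).
Scikit-learn estimators in this package instead expect samples as rows;
:meth:`ExpressionMatrix.to_samples` performs the transposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("counts", "cpm", "log2", "standardized", "pooled")

SUBTYPES = ("EBV", "MSI", "GS", "CIN")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} IDs: {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a value-scale tag.

    Parameters
    ----------
    data:
        DataFrame with gene IDs as the index and sample IDs as columns.
    scale:
        One of ``counts``, ``cpm``, ``log2``, ``standardized``, ``pooled``.
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.scale == "counts":
            if (values < 0).any():
                raise ValidationError("counts must be nonnegative")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_samples(self) -> pd.DataFrame:
        """Samples-as-rows view for scikit-learn style estimators."""
        return self.data.T

    def with_values(self, values: np.ndarray | pd.DataFrame, scale: str) -> "ExpressionMatrix":
        """New matrix with the same gene/sample axes and a new scale tag."""
        frame = pd.DataFrame(np.asarray(values, dtype=float),
                             index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(frame, scale=scale)


@dataclass
class MutationMatrix:
    """Binary gene x sample mutation indicators plus per-sample totals.

    ``total_mutations`` counts all mutations in the assayed region (not just
    the panel genes in ``indicator``), hence it must dominate the per-sample
    indicator column sums.  ``target_region_mb`` is the size of the sequenced
    coding territory in megabases, used to express burden as mutations/Mb.
    """

    indicator: pd.DataFrame
    total_mutations: pd.Series
    target_region_mb: float

    def __post_init__(self) -> None:
        _check_unique(self.indicator.index, "gene")
        _check_unique(self.indicator.columns, "sample")
        values = self.indicator.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("mutation indicators must be 0/1")
        if self.target_region_mb <= 0:
            raise ValidationError("target_region_mb must be positive")
        if not self.total_mutations.index.equals(self.indicator.columns):
            self.total_mutations = self.total_mutations.reindex(self.indicator.columns)
        if self.total_mutations.isna().any():
            raise ValidationError("total_mutations missing for some samples")
        colsums = self.indicator.sum(axis=0)
        if (self.total_mutations < colsums).any():
            bad = self.total_mutations.index[(self.total_mutations < colsums)].tolist()
            raise ValidationError(f"total_mutations below panel column sums for {bad[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.indicator.columns


@dataclass
class CohortFixture:
    """A simulated multi-cohort study: expression, annotation, mutations, truth.

    ``annotation`` has one row per sample with columns ``sample_id``,
    ``cohort``, ``histology``, ``subtype`` and ``cluster``; ``truth`` repeats
    the ground-truth subtype/cluster assignment used by recovery tests.
    ``signature_genes`` maps each subtype to the planted signature gene IDs.
    """

    expression: ExpressionMatrix
    annotation: pd.DataFrame
    mutations: MutationMatrix
    truth: pd.DataFrame
    signature_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = self.expression.samples
        if list(self.annotation["sample_id"]) != list(samples):
            raise ValidationError("annotation sample order does not match expression")
        if list(self.mutations.samples) != list(samples):
            raise ValidationError("mutation sample order does not match expression")
        if list(self.truth["sample_id"]) != list(samples):
            raise ValidationError("truth sample order does not match expression")
        bad = set(self.truth["subtype"]) - set(SUBTYPES)
        if bad:
            raise ValidationError(f"unknown subtypes in truth: {sorted(bad)}")
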