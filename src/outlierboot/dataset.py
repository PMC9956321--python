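"""Expression dataset container and tab-separated I/O.

The universal input of the package is a matrix of normalized expression
values (transcripts in rows, samples in columns) together with a sample
annotation table that assigns each sample to a study group and, for
simulated data, records which samples are planted outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Transcripts-by-samples expression matrix with per-sample group labels.

    Parameters
    ----------
    expression : pandas.DataFrame
        Real-valued matrix, one row per transcript (index = transcript ids),
        one column per sample (columns = sample ids). No missing values.
    groups : pandas.Series
        Group label per sample, indexed by sample id; must cover exactly the
        columns of ``expression``.
    is_true_outlier : pandas.Series or None
        Optional boolean flag per sample marking planted outliers (simulated
        data only).
    """

    expression: pd.DataFrame
    groups: pd.Series
    is_true_outlier: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.expression = pd.DataFrame(self.expression)
        self.groups = pd.Series(self.groups)
        if not self.expression.columns.equals(self.groups.index):
            # allow same set, different order
            if set(self.expression.columns) != set(self.groups.index):
                raise ValueError(
                    "group labels must be indexed by the expression columns"
                )
            self.groups = self.groups.reindex(self.expression.columns)
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.groups.isna().any():
            raise ValueError("every sample needs exactly one group label")
        if self.is_true_outlier is not None:
            self.is_true_outlier = (
                pd.Series(self.is_true_outlier)
                .reindex(self.expression.columns)
                .fillna(False)
                .astype(bool)
            )

    # ------------------------------------------------------------------ #
    @property
    def n_transcripts(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def transcript_ids(self) -> pd.Index:
        return self.expression.index

    def group_levels(self) -> list:
        return sorted(self.groups.unique().tolist())

    def values_samples_by_transcripts(self) -> np.ndarray:
        """Matrix oriented the sklearn way: samples in rows."""
        return np.ascontiguousarray(self.expression.to_numpy().T)

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        """Return a new dataset restricted to ``sample_ids`` (order kept)."""
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)!r}")
        return ExpressionDataset(
            expression=self.expression[sample_ids],
            groups=self.groups.loc[sample_ids],
            is_true_outlier=None
            if self.is_true_outlier is None
            else self.is_true_outlier.loc[sample_ids],
        )

    def drop_samples(self, sample_ids) -> "ExpressionDataset":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.subset_samples(keep)

    # ------------------------------------------------------------------ #
    def to_tsv(self, expression_path, metadata_path) -> None:
        """Write the expression matrix and the sample annotation as TSV.

        The expression file has the transcript id as first column; the
        metadata file has columns sample_id, group, is_true_outlier.
        """
        expr = self.expression.copy()
        expr.index.name = "transcript_id"
        expr.to_csv(expression_path, sep="\t")
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.groups.values,
                "is_true_outlier": (
                    self.is_true_outlier.values
                    if self.is_true_outlier is not None
                    else [False] * self.n_samples
                ),
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionDataset":
        expr = pd.read_csv(Path(expression_path), sep="\t", index_col=0)
        meta = pd.read_csv(Path(metadata_path), sep="\t")
        if "sample_id" not in meta.columns or "group" not in meta.columns:
            raise ValueError("metadata must contain sample_id and group columns")
        meta = meta.set_index("sample_id")
        groups = meta["group"].reindex(expr.columns)
        outl = None
        if "is_true_outlier" in meta.columns:
            outl = meta["is_true_outlier"].reindex(expr.columns).astype(bool)
        return cls(expression=expr, groups=groups, is_true_outlier=outl)
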