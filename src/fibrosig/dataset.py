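"""Core expression-data container.

A dataset couples a log2-scale gene-by-sample expression matrix with a
per-sample annotation table describing the study design (patient of
origin, anatomical tissue, disease group, serum condition).  All
downstream analyses — differential expression, classification, PCA —
consume this one container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: annotation columns required by the full study design
ANNOTATION_COLUMNS = ("patient", "tissue", "disease", "serum")


class DatasetError(ValueError):
    """Raised when an expression dataset violates its structural contract."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix plus sample annotation.

    Parameters
    ----------
    values
        DataFrame of log2 expression, rows indexed by gene ID, columns
        by sample ID.  Values must be finite.
    annotation
        DataFrame indexed by sample ID with at least the columns in
        :data:`ANNOTATION_COLUMNS`; every entry must be a non-empty
        string.  Sample order must match ``values.columns``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        v, a = self.values, self.annotation
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate gene IDs: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample IDs: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(v)
            raise DatasetError(f"non-numeric expression value at {bad}")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise DatasetError(
                f"non-finite expression value at gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )
        if list(a.index) != list(v.columns):
            raise DatasetError("annotation index must equal the sample columns, in order")
        missing = [c for c in ANNOTATION_COLUMNS if c not in a.columns]
        if missing:
            raise DatasetError(f"annotation missing columns: {missing}")
        for col in ANNOTATION_COLUMNS:
            bad = a[col].isna() | (a[col].astype(str).str.len() == 0)
            if bad.any():
                raise DatasetError(
                    f"empty annotation {col!r} for sample {a.index[bad][0]!r}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionDataset":
        """Restrict to the given genes (order = given order ∩ present)."""
        keep = [g for g in genes if g in self.values.index]
        return ExpressionDataset(self.values.loc[keep], self.annotation)

    def subset_samples(self, samples) -> "ExpressionDataset":
        keep = [s for s in samples if s in self.values.columns]
        return ExpressionDataset(self.values[keep], self.annotation.loc[keep])

    def subset_where(self, **conditions) -> "ExpressionDataset":
        """Subset samples by annotation equality, e.g. ``tissue="synovium"``."""
        mask = pd.Series(True, index=self.annotation.index)
        for col, val in conditions.items():
            if col not in self.annotation.columns:
                raise DatasetError(f"unknown annotation column {col!r}")
            mask &= self.annotation[col] == val
        return self.subset_samples(self.annotation.index[mask])


def _first_non_numeric(values: pd.DataFrame) -> str:
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        raw_na = values[col].isna()
        bad = coerced.isna() & ~raw_na
        if bad.any():
            return f"gene {values.index[bad][0]!r}, sample {col!r}"
    return "unknown position"
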