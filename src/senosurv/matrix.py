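"""Expression matrix container and TSV round-trip.

The whole package works on a features-by-samples table of nonnegative,
linear-scale intensities (MAS5-like microarray scale, or any gene-level
quantification after back-transformation).  A thin dataclass wraps a
:class:`pandas.DataFrame` so that validity (unique identifiers, finite
nonnegative values) is checked once at the boundary and every downstream
operation can rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Features x samples intensity table.

    Parameters
    ----------
    data
        DataFrame indexed by feature id (probe or gene symbol) with one
        column per sample.  Values are linear-scale intensities, >= 0.
    batch_of
        Optional mapping sample id -> dataset/batch label, aligned with
        the columns of ``data``.
    """

    data: pd.DataFrame
    batch_of: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (features x samples)")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.batch_of is not None:
            self.batch_of = pd.Series(self.batch_of)
            missing = self.data.columns.difference(self.batch_of.index)
            if len(missing):
                raise ValueError(f"batch_of lacks labels for samples: {list(missing)[:5]}")
            self.batch_of = self.batch_of.reindex(self.data.columns)

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order as given)."""
        batch = self.batch_of.reindex(sample_ids) if self.batch_of is not None else None
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), batch)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)].copy(), self.batch_of)

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, float_format: str = "%.6f") -> None:
        """Write as TSV: first column ``feature_id``, header row = sample ids."""
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format=float_format)

    @classmethod
    def from_tsv(cls, path: str | Path, batch_of: pd.Series | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df.astype(float), batch_of)
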