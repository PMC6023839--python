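"""Expression-matrix container and tab-separated I/O.

The whole pipeline operates on log2-scale expression matrices (features in
rows, samples in columns) with a two-level sample condition: ``relapse`` vs
``remission``.  The container is a thin wrapper around a pandas DataFrame
that enforces the invariants every downstream stage relies on: unique ids,
no missing values, and both conditions represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("relapse", "remission")


@dataclass
class ExpressionMatrix:
    """A log2 feature-by-sample expression matrix with condition labels.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples); index = feature ids,
        columns = sample ids, all finite floats.
    condition_of
        Mapping from sample id to ``"relapse"`` or ``"remission"``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.condition_of = dict(self.condition_of)
        self._validate()

    def _validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        bad = {s: c for s, c in self.condition_of.items()
               if s in self.values.columns and c not in CONDITIONS}
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")
        present = {self.condition_of[s] for s in self.values.columns}
        if set(CONDITIONS) - present:
            raise ValueError(
                f"both conditions must be represented, got only {sorted(present)}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Sub-matrix restricted to one condition's samples."""
        return self.values[self.samples_in(condition)]

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        """Row subset preserving the requested order."""
        feats = list(features)
        unknown = [f for f in feats if f not in self.values.index]
        if unknown:
            raise KeyError(f"unknown features: {unknown[:5]}")
        return ExpressionMatrix(self.values.loc[feats], self.condition_of)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, expr_path: str | Path, samples_path: str | Path | None = None,
               feature_col: str = "feature_id") -> None:
        df = self.values.copy()
        df.index.name = feature_col
        df.to_csv(expr_path, sep="\t", float_format="%.10g")
        if samples_path is not None:
            sample_table(self).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path: str | Path,
                 samples_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        samples = pd.read_csv(samples_path, sep="\t", dtype=str)
        if not {"sample_id", "condition"} <= set(samples.columns):
            raise ValueError("sample table needs columns sample_id, condition")
        cond = dict(zip(samples["sample_id"], samples["condition"]))
        return cls(df, cond)


def sample_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "condition": [matrix.condition_of[s] for s in matrix.sample_ids],
        }
    )
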