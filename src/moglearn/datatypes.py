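"""Core in-memory containers shared across the pipeline.

Omics layers travel as :class:`OmicsMatrix` (a thin wrapper around a
samples x features :class:`pandas.DataFrame`); the inner-joined multi-omics
matrix is an :class:`IntegratedDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical ordering of omics layers throughout the package
LAYER_ORDER = ("mrna", "mirna", "methylation")

#: layers carrying non-negative integer sequencing counts
COUNT_LAYERS = ("mrna", "mirna")


@dataclass
class OmicsMatrix:
    """One omics layer: samples in rows, molecular features in columns.

    Parameters
    ----------
    layer
        Layer tag, one of ``"mrna"``, ``"mirna"``, ``"methylation"`` (other
        tags are allowed for generic use).
    values
        DataFrame indexed by sample ID with feature IDs as columns.
    """

    layer: str
    values: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.loc[:, list(feature_ids)])

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, layer: str, path) -> "OmicsMatrix":
        df = pd.read_csv(path, index_col=0)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s) in {path}: {dup}")
        return cls(layer, df)


@dataclass
class IntegratedDataset:
    """Inner-joined multi-omics feature matrix with class labels.

    ``X`` holds one row per sample retained in *all* requested layers;
    ``feature_origin`` tags every column with the layer it came from, in
    layer order.
    """

    X: pd.DataFrame
    feature_origin: pd.Series  # index = X.columns, values = layer tag
    labels: pd.Series  # index = X.index, values = class label

    def __post_init__(self) -> None:
        if not self.X.columns.equals(self.feature_origin.index):
            raise ValueError("feature_origin must be indexed by X's columns")
        if not self.X.index.equals(self.labels.index):
            raise ValueError("labels must be indexed by X's rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels.to_numpy())

    def layer_columns(self, layer: str) -> pd.Index:
        return self.feature_origin.index[self.feature_origin == layer]


@dataclass
class Standardizer:
    """Per-feature z-scoring whose statistics come from training rows only.

    Keeping the fitted mean/scale separate from the data guarantees the
    leakage contract: test rows never influence the statistics applied to
    them.
    """

    mean_: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray, rows: np.ndarray | None = None) -> "Standardizer":
        sub = X if rows is None else X[rows]
        self.mean_ = sub.mean(axis=0)
        scale = sub.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (X - self.mean_) / self.scale_
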