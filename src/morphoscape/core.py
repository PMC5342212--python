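"""Shared containers: labeled symmetric distance matrices.

A :class:`DistanceMatrix` is the common currency of the pipeline — shape,
size, genetic, geographic and environmental dissimilarities all travel in
this container so that aggregation, residualization and regression code can
stay agnostic of what the numbers mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative-or-signed distance matrix.

    Parameters
    ----------
    labels : sequence of str
        Ordered unit identifiers (individuals or populations).
    values : (n, n) ndarray
        Symmetric matrix with zero diagonal.  Entries may be negative for
        residual distances.
    metric_name : str
        Free-text description of the metric.
    """

    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in DistanceMatrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in DistanceMatrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("matrix diagonal is not zero")
        # canonicalize: exact symmetry, exact zero diagonal
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Reorder/subset to the given labels."""
        idx = [self.index_of(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.metric_name
        )

    def condensed(self) -> np.ndarray:
        """Upper triangle (excluding diagonal), row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path, metric_name: str = "distance") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), metric_name)

    @classmethod
    def from_condensed(
        cls, labels: Sequence[str], condensed: np.ndarray, metric_name: str = "distance"
    ) -> "DistanceMatrix":
        n = len(labels)
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed vector length does not match label count")
        vals[iu] = condensed
        vals = vals + vals.T
        return cls(list(labels), vals, metric_name)
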