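"""Labelled symmetric matrices shared across the statistics and distance modules."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PairwiseMatrix:
    """A labelled symmetric population-by-population matrix.

    Carries FST, Jost's D, p-values or distances.  ``diagonal`` records the
    semantics of the main diagonal: "zero" for distances, "undefined" for
    quantities that have no self-comparison (stored as NaN).
    """

    labels: list[str]
    values: np.ndarray
    diagonal: str = "zero"  # "zero" | "undefined"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-10
        ):
            raise ValueError("matrix is not symmetric")
        if self.diagonal == "undefined":
            np.fill_diagonal(self.values, np.nan)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, keep: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(k) for k in keep]
        return PairwiseMatrix(
            list(keep), self.values[np.ix_(idx, idx)], self.diagonal, self.name
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "PairwiseMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), **kw)

    @classmethod
    def read_csv(cls, path, **kw) -> "PairwiseMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0), **kw)


def from_condensed(labels: list[str], tri: np.ndarray, **kw) -> PairwiseMatrix:
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = tri
    m[(iu[1], iu[0])] = tri
    return PairwiseMatrix(list(labels), m, **kw)
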