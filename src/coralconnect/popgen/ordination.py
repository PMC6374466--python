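"""Principal coordinate analysis (classical metric scaling) of a distance matrix."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ..matrices import PairwiseMatrix


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x axes
    percent_variance: np.ndarray    # % of positive-eigenvalue variance per axis
    eigenvalues: np.ndarray


def pcoa(distance: PairwiseMatrix | np.ndarray, n_axes: int = 2,
         labels: list[str] | None = None) -> PCoAResult:
    """Classical metric scaling of a symmetric distance matrix.

    Double-centres the Gower matrix and eigendecomposes it (delegated to
    scikit-bio); axes are ordered by eigenvalue and the explained variance is
    relative to the sum of positive eigenvalues.
    """
    if isinstance(distance, PairwiseMatrix):
        labels = distance.labels
        mat = distance.values
    else:
        mat = np.asarray(distance, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(mat.shape[0])]
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(mat, ids=labels)
    with np.errstate(invalid="ignore"):   # all-zero matrix: 0/0 proportions
        res = _skbio_pcoa(dm, number_of_dimensions=min(n_axes, len(labels) - 1))
    eig = res.eigvals.to_numpy()
    pos_sum = eig[eig > 0].sum()
    n_axes = min(n_axes, res.samples.shape[1])
    coords = res.samples.iloc[:, :n_axes]
    coords.index = labels
    pct = (
        100.0 * eig[:n_axes] / pos_sum if pos_sum > 0
        else np.zeros(n_axes)
    )
    return PCoAResult(coords, pct, eig)
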