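"""Connectivity matrices: per-year assembly, multi-year averaging,
multi-generation iteration, and region aggregation.

The single-generation entry (i, j) is the probability that a particle
released at site i settles at site j.  The multi-generation form answers a
different question — has a lineage starting at i reached j within g
generations — and is computed as monotone reachability on the
row-normalised settlement chain with the saturating combine
a (+) b = a + b - a*b, which grows monotonically and stabilises.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import ParticleFate


@dataclass
class ConnectivityMatrix:
    sites: list[str]
    values: np.ndarray            # (n, n) source x sink
    year: int | None = None
    generation: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sites)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match site list")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-9).any():
            raise ValueError("connectivity entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path, **kw) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), **kw)


def build_connectivity(
    fates: list[ParticleFate],
    sites: list[str],
    released: dict[str, int] | None = None,
    year: int | None = None,
) -> ConnectivityMatrix:
    """One-year matrix: settled(i -> j) / released(i).

    ``released`` defaults to the per-source fate counts (settled + expired +
    exited); sites that released nothing get a zero row with a warning.
    """
    idx = {s: k for k, s in enumerate(sites)}
    n = len(sites)
    settled = np.zeros((n, n))
    counts = {s: 0 for s in sites}
    for f in fates:
        counts[f.source] = counts.get(f.source, 0) + 1
        if f.outcome == "settled":
            settled[idx[f.source], idx[f.dest]] += 1
    if released is None:
        released = counts
    vals = np.zeros((n, n))
    for s, k in idx.items():
        r = released.get(s, 0)
        if r == 0:
            warnings.warn(f"site {s!r} released no particles; zero row")
        else:
            vals[k] = settled[k] / r
    return ConnectivityMatrix(list(sites), vals, year=year)


def average_years(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean over years; no-spawning site-years contribute their
    zero rows and stay in the denominator."""
    if not matrices:
        raise ValueError("no matrices to average")
    sites = matrices[0].sites
    for m in matrices[1:]:
        if m.sites != sites:
            raise ValueError("matrices must share the same site list")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(list(sites), mean)


def iterate_generations(
    C: ConnectivityMatrix, n_gen: int = 1000, tol: float = 0.0
) -> tuple[ConnectivityMatrix, list[float]]:
    """Stabilised multi-generation reachability of the settlement chain.

    A_1 = C;  A_{g+1} = A_g (+) (A_g @ C_hat), where C_hat is C row-
    normalised over settling particles and (+) is the element-wise
    saturating combine.  Entries are monotone non-decreasing in g and capped
    at 1; iteration stops early when the max element change drops below
    ``tol``.  Returns (matrix, per-generation max-change trace).
    """
    vals = C.values
    if vals.shape[0] != vals.shape[1]:
        raise ValueError("matrix must be square")
    if (vals < 0).any():
        raise ValueError("entries must be non-negative")
    rows = vals.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        chat = np.where(rows > 0, vals / rows, 0.0)
    A = vals.copy()
    trace: list[float] = []
    for _ in range(1, n_gen):
        step = np.clip(A @ chat, 0.0, 1.0)
        new = A + step - A * step
        new = np.clip(new, 0.0, 1.0)
        change = float(np.abs(new - A).max())
        trace.append(change)
        A = new
        if change < tol:
            break
    return (
        ConnectivityMatrix(list(C.sites), A, generation=len(trace) + 1),
        trace,
    )


def aggregate_regions(
    C: ConnectivityMatrix, region_map: dict[str, str]
) -> ConnectivityMatrix:
    """Region-level matrix: mean over member source sites of the summed
    sink-site probabilities within the sink region."""
    missing = [s for s in C.sites if s not in region_map]
    if missing:
        raise ValueError(f"sites without a region: {missing}")
    regions = list(dict.fromkeys(region_map[s] for s in C.sites))
    out = np.zeros((len(regions), len(regions)))
    for ri, r in enumerate(regions):
        rows = [k for k, s in enumerate(C.sites) if region_map[s] == r]
        for sj, t in enumerate(regions):
            cols = [k for k, s in enumerate(C.sites) if region_map[s] == t]
            out[ri, sj] = C.values[np.ix_(rows, cols)].sum(axis=1).mean()
    return ConnectivityMatrix(regions, np.clip(out, 0.0, 1.0))


def conservation_check(fates: list[ParticleFate],
                       released: dict[str, int]) -> None:
    """Assert settled + expired + exited = released for every source."""
    got: dict[str, int] = {}
    for f in fates:
        got[f.source] = got.get(f.source, 0) + 1
    for s, n in released.items():
        if got.get(s, 0) != n:
            raise AssertionError(
                f"conservation violated for {s}: {got.get(s, 0)} fates, "
                f"{n} released"
            )
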