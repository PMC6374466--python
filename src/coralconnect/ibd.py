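"""Isolation by distance: geographic distance predictors and the Mantel test.

Three predictors of pairwise genetic differentiation are supported:
great-circle distance, shortest sea-path distance (Dijkstra on the sea-cell
lattice, replacing hand-measured around-land routes with a reproducible
computation), and a dissimilarity derived from simulated multi-generation
larval connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .matrices import PairwiseMatrix

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _coord_arrays(coords: dict[str, tuple[float, float]] | pd.DataFrame):
    if isinstance(coords, pd.DataFrame):
        labels = list(coords.index.astype(str))
        lat = coords["lat"].to_numpy(dtype=float)
        lon = coords["lon"].to_numpy(dtype=float)
    else:
        labels = list(coords)
        lat = np.array([coords[k][0] for k in labels], dtype=float)
        lon = np.array([coords[k][1] for k in labels], dtype=float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    return labels, lat, lon


def great_circle_matrix(coords) -> PairwiseMatrix:
    """Haversine distances (km) between sites; ``coords`` maps label ->
    (lat, lon) or is a DataFrame with lat/lon columns."""
    labels, lat, lon = _coord_arrays(coords)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(labels, d, diagonal="zero", name="great_circle_km")


def sea_path_matrix(coords, mask: np.ndarray, lat_grid: np.ndarray,
                    lon_grid: np.ndarray, snap_radius_cells: int = 3
                    ) -> PairwiseMatrix:
    """Shortest sea-path distances (km) on the 8-connected sea-cell lattice.

    ``mask`` is True on land.  Each site is snapped to the nearest sea cell
    within ``snap_radius_cells``; a pair with no sea route raises an error
    naming the pair.
    """
    labels, lat, lon = _coord_arrays(coords)
    ny, nx = mask.shape
    sea = ~mask

    def node(i, j):
        return i * nx + j

    # 8-connected edges between sea cells, haversine weights
    rows, cols, w = [], [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            i0 = np.arange(max(0, -di), min(ny, ny - di))
            j0 = np.arange(max(0, -dj), min(nx, nx - dj))
            II, JJ = np.meshgrid(i0, j0, indexing="ij")
            ok = sea[II, JJ] & sea[II + di, JJ + dj]
            II, JJ = II[ok], JJ[ok]
            rows.append(node(II, JJ))
            cols.append(node(II + di, JJ + dj))
            w.append(haversine_km(lat_grid[II], lon_grid[JJ],
                                  lat_grid[II + di], lon_grid[JJ + dj]))
    graph = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    ).tocsr()

    cell = float(np.diff(lat_grid).mean())
    site_nodes = []
    for k, name in enumerate(labels):
        i = int(np.argmin(np.abs(lat_grid - lat[k])))
        j = int(np.argmin(np.abs(lon_grid - lon[k])))
        found = None
        for r in range(snap_radius_cells + 1):
            ii = np.arange(max(0, i - r), min(ny, i + r + 1))
            jj = np.arange(max(0, j - r), min(nx, j + r + 1))
            II, JJ = np.meshgrid(ii, jj, indexing="ij")
            cand = np.argwhere(sea[II, JJ])
            if len(cand):
                dcand = [
                    haversine_km(lat[k], lon[k], lat_grid[II[a, b]],
                                 lon_grid[JJ[a, b]])
                    for a, b in cand
                ]
                a, b = cand[int(np.argmin(dcand))]
                found = (int(II[a, b]), int(JJ[a, b]))
                break
        if found is None:
            raise ValueError(f"site {name!r} has no nearby sea cell")
        site_nodes.append(node(*found))

    dist = dijkstra(graph, directed=False, indices=site_nodes)
    d = dist[:, site_nodes]
    if np.isinf(d).any():
        bad = np.argwhere(np.isinf(d))
        a, b = bad[0]
        raise ValueError(
            f"no sea route between {labels[a]!r} and {labels[b]!r}"
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(labels, d, diagonal="zero", name="sea_path_km")


def connectivity_distance(C) -> PairwiseMatrix:
    """Dissimilarity from an (iterated) connectivity matrix.

    d_ij = -log((C_ij + C_ji)/2 + eps) with eps = half the smallest positive
    symmetrised entry, which places zero-flow pairs strictly beyond every
    connected pair without infinities.
    """
    sites = C.sites
    sym = (C.values + C.values.T) / 2.0
    off = sym[~np.eye(len(sites), dtype=bool)]
    pos = off[off > 0]
    if len(pos) == 0:
        raise ValueError("connectivity matrix has no positive flow")
    eps = pos.min() / 2.0
    d = -np.log(sym + eps)
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(list(sites), d, diagonal="zero",
                          name="connectivity_dissimilarity")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    excluded: list[str]
    tail: str = "greater"


def mantel(
    genetic: PairwiseMatrix,
    geographic: PairwiseMatrix,
    n_perm: int = 10_000,
    exclude: list[str] | tuple = (),
    seed: int | None = None,
    linearize_fst: bool = False,
) -> MantelResult:
    """One-tailed Mantel permutation test of matrix association.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    null distribution permutes the row/column order of one matrix jointly;
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).  ``linearize_fst`` applies
    the FST/(1-FST) transform to the genetic matrix first (off by default;
    raw FST is the regression variable here).
    """
    keep = [l for l in genetic.labels if l not in set(exclude)]
    if len(keep) < 4:
        raise ValueError("need at least 4 populations after exclusions")
    if set(keep) - set(geographic.labels):
        raise ValueError("matrices do not share the retained labels")
    g = genetic.submatrix(keep).values.copy()
    if linearize_fst:
        g = g / (1.0 - g)
    x = geographic.submatrix(keep).values
    n = len(keep)
    iu = np.triu_indices(n, k=1)
    gv = g[iu]
    xv = x[iu]

    def corr(mat):
        a = mat[iu]
        if a.std() == 0 or xv.std() == 0:
            return 0.0
        return float(np.corrcoef(a, xv)[0, 1])

    r_obs = corr(g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(g[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (1 + hits) / (n_perm + 1), n_perm, list(exclude))
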