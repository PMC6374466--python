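"""Synthetic fixtures with known truth: genotypes, ocean fields, SST, moons.

Everything the pipeline consumes can be generated here so the full analysis
runs, and is checkable against planted parameters, without any external
data.  Genotypes use a Balding-Nichols parameterisation (island layout),
which makes the planted divergence an analytic FST truth, or serial
founder/drift resampling (linear stepping-stone), which produces the
edge-ward decline of diversity expected under restricted neighbour
migration.  The ocean generator builds a divergence-free poleward jet with
seasonal, latitude-dependent SST — a deliberately minimal western-boundary
-current stand-in, not mesoscale oceanography.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, Polygon

from .genotypes import GenotypeTable

SYNODIC_DAYS = 29.530588

REGION_DEFAULTS = ("subtropical", "pre_existing_temperate", "recent_temperate")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class LineageSpec:
    """A second, diverged allele-frequency pool plus per-individual admixture.

    ``admixture`` maps population name -> per-individual proportion of the
    second lineage (length n_per_pop).  Individuals draw each gene copy from
    pool 2 with their admixture probability.
    """

    divergence: float = 0.3
    admixture: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class SimGenotypeConfig:
    n_pops: int = 13
    n_per_pop: int = 20
    n_loci: int = 8
    alleles_per_locus: int = 8
    fst_target: float = 0.108
    layout: str = "island"                  # "island" | "linear-stepping-stone"
    clone_spec: dict[str, list[int]] = field(default_factory=dict)
    lineage_spec: LineageSpec | None = None
    missing_rate: float = 0.0
    seed: int = 0
    pop_names: list[str] | None = None
    # synthetic geography: populations on a south->north line along a coast
    lat_range: tuple[float, float] = (24.5, 34.5)
    lon_range: tuple[float, float] = (124.0, 139.0)

    def __post_init__(self) -> None:
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must lie in [0, 1)")
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.layout not in ("island", "linear-stepping-stone"):
            raise ValueError(f"unknown layout {self.layout!r}")
        names = self.pop_names or [f"P{i + 1:02d}" for i in range(self.n_pops)]
        if len(names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")
        self.pop_names = names
        for pop, ramets in self.clone_spec.items():
            if pop not in names:
                raise ValueError(f"clone_spec population {pop!r} unknown")
            extra = sum(r - 1 for r in ramets)
            if any(r < 2 for r in ramets):
                raise ValueError("each clone_spec entry needs >= 2 ramets")
            if extra >= self.n_per_pop or len(ramets) + (
                self.n_per_pop - extra - len(ramets)
            ) < len(ramets):
                raise ValueError(
                    f"clone_spec for {pop!r} exceeds n_per_pop={self.n_per_pop}"
                )


def _pop_frequencies(cfg: SimGenotypeConfig, rng: np.random.Generator,
                     ancestral: np.ndarray) -> np.ndarray:
    """(n_pops, n_loci, k) subpopulation allele frequencies."""
    P, L, K = cfg.n_pops, cfg.n_loci, cfg.alleles_per_locus
    F = cfg.fst_target
    freqs = np.empty((P, L, K))
    if cfg.layout == "island":
        if F == 0:
            freqs[:] = ancestral[None]
        else:
            conc = (1.0 - F) / F
            for l in range(L):
                alpha = np.clip(ancestral[l] * conc, 1e-6, None)
                freqs[:, l, :] = rng.dirichlet(alpha, size=P)
    else:
        # serial founder/drift: binomial resampling of 2*Ne gene copies per
        # link; per-step drift 1/(2*Ne) = fst_target/(n_pops-1), so the
        # divergence accumulated across the whole chain is about fst_target
        ne = (
            max(1, round((cfg.n_pops - 1) / (2 * F))) if F > 0 and cfg.n_pops > 1
            else None
        )
        freqs[0] = ancestral
        for p in range(1, P):
            if ne is None:
                freqs[p] = freqs[p - 1]
            else:
                for l in range(L):
                    draw = rng.multinomial(2 * ne, freqs[p - 1, l])
                    freqs[p, l] = draw / (2.0 * ne)
    return freqs


def _region_of(i: int, n: int) -> str:
    # south -> north: roughly the study's split of 13 populations into
    # 3 subtropical, 6 pre-existing temperate, 4 recently expanded
    bounds = (round(n * 3 / 13), round(n * 9 / 13))
    if i < bounds[0]:
        return "subtropical"
    if i < bounds[1]:
        return "pre_existing_temperate"
    return "recent_temperate"


def _sample_alleles(rng: np.random.Generator, p: np.ndarray, shape) -> np.ndarray:
    """Vectorised categorical draw via inverse-CDF."""
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(shape), side="right").astype(np.int32)


def generate_genotypes(cfg: SimGenotypeConfig) -> GenotypeTable:
    """Simulate a GenotypeTable with planted structure.

    The returned table carries a ``sim_truth`` attribute with the ancestral
    and per-population allele frequencies and (when a lineage_spec is given)
    the true admixture Q-matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    P, N, L, K = cfg.n_pops, cfg.n_per_pop, cfg.n_loci, cfg.alleles_per_locus
    ancestral = rng.dirichlet(np.ones(K), size=L)        # (L, K)
    freqs = _pop_frequencies(cfg, rng, ancestral)
    lineage_freqs = None
    if cfg.lineage_spec is not None:
        F2 = cfg.lineage_spec.divergence
        conc = (1.0 - F2) / F2 if F2 > 0 else None
        lineage_freqs = np.empty((L, K))
        for l in range(L):
            lineage_freqs[l] = (
                rng.dirichlet(np.clip(ancestral[l] * conc, 1e-6, None))
                if conc is not None else ancestral[l]
            )

    individuals: list[str] = []
    pops: list[str] = []
    calls_rows: list[np.ndarray] = []
    q_rows: dict[str, float] = {}

    for pi, pop in enumerate(cfg.pop_names):
        ramets = cfg.clone_spec.get(pop, [])
        n_unique = N - sum(r - 1 for r in ramets)
        q_pop = (
            cfg.lineage_spec.admixture.get(pop, [0.0] * N)
            if cfg.lineage_spec else [0.0] * N
        )
        unique_calls = np.zeros((n_unique, L, 2), dtype=np.int32)
        q_arr = np.array(
            [q_pop[u] if u < len(q_pop) else 0.0 for u in range(n_unique)]
        )
        for l in range(L):
            # each gene copy drawn from lineage pool 2 with probability q
            draws = 1 + _sample_alleles(rng, freqs[pi, l], (n_unique, 2))
            if lineage_freqs is not None and (q_arr > 0).any():
                from_l2 = rng.random((n_unique, 2)) < q_arr[:, None]
                if from_l2.any():
                    alt = 1 + _sample_alleles(rng, lineage_freqs[l], (n_unique, 2))
                    draws = np.where(from_l2, alt, draws)
            unique_calls[:, l, :] = draws
        if cfg.missing_rate > 0:
            miss = rng.random((n_unique, L)) < cfg.missing_rate
            unique_calls[miss] = 0
        # ramets: exact duplicates of the first len(ramets) genets
        order: list[tuple[np.ndarray, float]] = []
        for u in range(n_unique):
            order.append((unique_calls[u], q_pop[u] if u < len(q_pop) else 0.0))
            if u < len(ramets):
                for _ in range(ramets[u] - 1):
                    order.append(
                        (unique_calls[u], q_pop[u] if u < len(q_pop) else 0.0)
                    )
        for k, (row, q) in enumerate(order):
            ind = f"{pop}_{k + 1:03d}"
            individuals.append(ind)
            pops.append(pop)
            calls_rows.append(row)
            q_rows[ind] = q

    lats = np.linspace(*cfg.lat_range, P)
    lons = np.linspace(*cfg.lon_range, P)
    region = {p: _region_of(i, P) for i, p in enumerate(cfg.pop_names)}
    coords = {
        p: (float(lats[i]), float(lons[i])) for i, p in enumerate(cfg.pop_names)
    }
    table = GenotypeTable(
        individuals, [f"L{l + 1:02d}" for l in range(L)],
        np.array(calls_rows), np.array(pops, dtype=object), region, coords,
    )
    table.sim_truth = {
        "ancestral": ancestral,
        "pop_freqs": freqs,
        "lineage_freqs": lineage_freqs,
        "q": pd.Series(q_rows, name="lineage2"),
    }
    return table


def true_qmatrix(table: GenotypeTable, k_values=(2, 3)) -> dict[int, pd.DataFrame]:
    """Q-matrix blocks from the generator's planted admixture.

    Cluster 0 is the focal ("green") lineage at every K; the remaining
    membership is split evenly over the other clusters.
    """
    q2 = table.sim_truth["q"]
    blocks = {}
    for k in k_values:
        cols = np.zeros((len(q2), k))
        cols[:, 0] = 1.0 - q2.values
        for j in range(1, k):
            cols[:, j] = q2.values / (k - 1)
        blocks[k] = pd.DataFrame(
            cols, index=q2.index, columns=[f"cluster{j}" for j in range(k)]
        )
    return blocks


# ---------------------------------------------------------------------------
# Ocean fields and SST
# ---------------------------------------------------------------------------

@dataclass
class SimOceanConfig:
    lat_range: tuple[float, float] = (24.0, 35.0)
    lon_range: tuple[float, float] = (124.0, 140.0)
    cell_deg: float = 1.0 / 12.0
    t0: date = date(2001, 1, 1)
    n_days: int = 365
    field_step_days: float = 1.0
    # jet: core path as (lat, lon) waypoints, flow poleward along the path
    jet_path: tuple[tuple[float, float], ...] = ((24.0, 128.0), (35.0, 133.0))
    jet_width_deg: float = 0.8
    jet_speed: float = 0.4                   # m/s at the core
    eddy_amplitude: float = 0.0              # m/s rms of seeded noise
    land_polygons: tuple = ()                # ((lon, lat), ...) rings
    sst_mean_at_ref: float = 24.0            # deg C at sst_lat_ref
    sst_lat_ref: float = 24.0
    sst_lat_gradient: float = -0.45          # deg C per degree latitude north
    sst_amplitude: float = 4.0
    sst_phase_day: int = 227                 # mid-August peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_deg <= 0:
            raise ValueError("cell size must be positive")
        if self.jet_speed < 0:
            raise ValueError("peak speed must be >= 0")
        if (self.lat_range[1] <= self.lat_range[0]
                or self.lon_range[1] <= self.lon_range[0]):
            raise ValueError("empty grid")


def _jet_core_lon(cfg: SimOceanConfig, lat: np.ndarray) -> np.ndarray:
    path = np.asarray(cfg.jet_path)
    return np.interp(lat, path[:, 0], path[:, 1])


def _jet_slope(cfg: SimOceanConfig, lat: np.ndarray) -> np.ndarray:
    """d(core_lon)/d(lat) of the path at given latitudes."""
    eps = 1e-4
    return (_jet_core_lon(cfg, lat + eps) - _jet_core_lon(cfg, lat - eps)) / (2 * eps)


def generate_ocean(cfg: SimOceanConfig,
                   sites: pd.DataFrame | None = None):
    """Build (CurrentField dataset, per-site SST DataFrame).

    The field is an xarray Dataset with u(time, lat, lon), v, mask(lat, lon)
    [True = land], time in days since ``cfg.t0``.  The jet flows poleward
    along the configured core path with a Gaussian cross-section; u/v vanish
    on land.  ``sites`` (columns site, lat, lon) selects the SST series; with
    None the SST frame is empty.
    """
    lat = np.arange(cfg.lat_range[0] + cfg.cell_deg / 2, cfg.lat_range[1],
                    cfg.cell_deg)
    lon = np.arange(cfg.lon_range[0] + cfg.cell_deg / 2, cfg.lon_range[1],
                    cfg.cell_deg)
    if len(lat) == 0 or len(lon) == 0:
        raise ValueError("empty grid")
    time = np.arange(0.0, cfg.n_days, cfg.field_step_days)
    LON, LAT = np.meshgrid(lon, lat)

    core = _jet_core_lon(cfg, LAT)
    amp = cfg.jet_speed * np.exp(-0.5 * ((LON - core) / cfg.jet_width_deg) ** 2)
    slope = _jet_slope(cfg, LAT)
    # tangent in local metric coordinates: dx = slope*cos(lat) per unit lat
    tx = slope * np.cos(np.radians(LAT))
    norm = np.sqrt(1.0 + tx ** 2)
    u0 = amp * tx / norm
    v0 = amp / norm

    mask = np.zeros(LAT.shape, dtype=bool)
    for ring in cfg.land_polygons:
        poly = Polygon(ring)
        # cheap rasterisation over the bounding box only
        minx, miny, maxx, maxy = poly.bounds
        box = (LON >= minx) & (LON <= maxx) & (LAT >= miny) & (LAT <= maxy)
        for i, j in zip(*np.nonzero(box)):
            if poly.contains(Point(LON[i, j], LAT[i, j])):
                mask[i, j] = True

    rng = np.random.default_rng(cfg.seed)
    nt = len(time)
    u = np.broadcast_to(u0, (nt,) + u0.shape).copy()
    v = np.broadcast_to(v0, (nt,) + v0.shape).copy()
    if cfg.eddy_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        for t in range(nt):
            nu = gaussian_filter(rng.standard_normal(u0.shape), 3.0)
            nv = gaussian_filter(rng.standard_normal(u0.shape), 3.0)
            scale = cfg.eddy_amplitude / max(nu.std(), 1e-12)
            u[t] += nu * scale
            v[t] += nv * scale
    u[:, mask] = 0.0
    v[:, mask] = 0.0

    field = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), u.astype(np.float32)),
            "v": (("time", "lat", "lon"), v.astype(np.float32)),
            "mask": (("lat", "lon"), mask),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"t0": cfg.t0.isoformat(), "cell_deg": cfg.cell_deg},
    )

    if sites is not None and len(sites):
        days = np.arange(cfg.n_days)
        dates = pd.to_datetime(cfg.t0) + pd.to_timedelta(days, unit="D")
        doy = dates.dayofyear.to_numpy()
        data = {}
        for _, row in sites.iterrows():
            data[row["site"]] = sst_at(cfg, float(row["lat"]), doy)
        sst = pd.DataFrame(data, index=dates)
    else:
        sst = pd.DataFrame()
    return field, sst


def sst_at(cfg: SimOceanConfig, lat: float, day_of_year: np.ndarray) -> np.ndarray:
    """SST closed form: mean(lat) + amplitude*sin(2*pi*(doy - phase)/365.25)."""
    mean = cfg.sst_mean_at_ref + cfg.sst_lat_gradient * (lat - cfg.sst_lat_ref)
    return mean + cfg.sst_amplitude * np.sin(
        2 * np.pi * (np.asarray(day_of_year) - cfg.sst_phase_day) / 365.25
    )


# ---------------------------------------------------------------------------
# Full-moon table
# ---------------------------------------------------------------------------

def generate_moon_table(start: date, end: date,
                        reference_full_moon: date) -> pd.DatetimeIndex:
    """Full-moon dates as reference + k * 29.530588 d, truncated to [start, end].

    A fixed synodic-period arithmetic progression, not an ephemeris: exact
    lunar dates are irrelevant to the scheduling logic being exercised.
    """
    if start >= end:
        raise ValueError("start must precede end")
    ref = pd.Timestamp(reference_full_moon)
    t_start, t_end = pd.Timestamp(start), pd.Timestamp(end)
    k_min = int(np.floor((t_start - ref).days / SYNODIC_DAYS)) - 1
    k_max = int(np.ceil((t_end - ref).days / SYNODIC_DAYS)) + 1
    moons = [
        ref + pd.to_timedelta(k * SYNODIC_DAYS, unit="D")
        for k in range(k_min, k_max + 1)
    ]
    moons = [m for m in moons if t_start <= m <= t_end]
    return pd.DatetimeIndex(moons)
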