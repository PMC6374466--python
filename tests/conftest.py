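import numpy as np
import pandas as pd
import pytest
import xarray as xr

from coralconnect.dispersal import CurrentField, HabitatGrid
from coralconnect.genotypes import GenotypeTable


def make_table(pop_calls: dict[str, list[list[tuple[int, int]]]],
               loci: list[str] | None = None,
               region: dict[str, str] | None = None,
               coords: dict[str, tuple[float, float]] | None = None
               ) -> GenotypeTable:
    """Build a GenotypeTable from {population: [per-individual call rows]}."""
    individuals, pops, rows = [], [], []
    for pop, people in pop_calls.items():
        for k, calls in enumerate(people):
            individuals.append(f"{pop}_{k + 1:03d}")
            pops.append(pop)
            rows.append(calls)
    n_loci = len(rows[0])
    loci = loci or [f"L{l + 1:02d}" for l in range(n_loci)]
    return GenotypeTable(
        individuals, loci, np.array(rows, dtype=np.int32),
        np.array(pops, dtype=object), region or {}, coords or {},
    )


def uniform_field(u=0.0, v=0.0, lat=(29.0, 31.0), lon=(129.0, 131.0),
                  cell=0.25, n_days=60, mask_fn=None, t0="2001-01-01"):
    """A constant-velocity test field, optionally with a land mask."""
    lat_c = np.arange(lat[0] + cell / 2, lat[1], cell)
    lon_c = np.arange(lon[0] + cell / 2, lon[1], cell)
    time = np.arange(0.0, n_days, 1.0)
    shape = (len(time), len(lat_c), len(lon_c))
    mask = np.zeros((len(lat_c), len(lon_c)), dtype=bool)
    if mask_fn is not None:
        LON, LAT = np.meshgrid(lon_c, lat_c)
        mask = mask_fn(LAT, LON)
    uu = np.full(shape, u, dtype=np.float32)
    vv = np.full(shape, v, dtype=np.float32)
    uu[:, mask] = 0.0
    vv[:, mask] = 0.0
    ds = xr.Dataset(
        {"u": (("time", "lat", "lon"), uu),
         "v": (("time", "lat", "lon"), vv),
         "mask": (("lat", "lon"), mask)},
        coords={"time": time, "lat": lat_c, "lon": lon_c},
        attrs={"t0": t0, "cell_deg": cell},
    )
    return CurrentField(ds)


def habitat_of(sites):
    """sites: list of (name, lat, lon, region)."""
    return HabitatGrid(pd.DataFrame(
        sites, columns=["site", "lat", "lon", "region"]
    ))


@pytest.fixture
def two_pop_toy():
    """Two populations, one locus, hand-countable allele frequencies."""
    return make_table({
        "A": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 1)], [(1, 2)]],
        "B": [[(2, 2)], [(2, 3)], [(3, 3)], [(2, 2)], [(2, 3)]],
    })
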