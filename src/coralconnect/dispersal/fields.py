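"""Gridded current fields and the habitat-cell grid."""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
import xarray as xr


@dataclass
class CurrentField:
    """Surface velocity field on a regular lat/lon grid.

    Wraps an xarray Dataset with variables u(time, lat, lon), v, and a
    boolean land mask(lat, lon); ``time`` is days since ``t0``.
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        for var in ("u", "v", "mask"):
            if var not in self.ds:
                raise ValueError(f"field dataset lacks variable {var!r}")
        sea = ~self.ds["mask"].values
        for var in ("u", "v"):
            vals = self.ds[var].values
            if not np.isfinite(vals[:, sea]).all():
                raise ValueError(f"{var} has non-finite values on sea cells")

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def time(self) -> np.ndarray:
        return self.ds["time"].values

    @property
    def mask(self) -> np.ndarray:
        return self.ds["mask"].values

    @property
    def t0(self) -> pd.Timestamp:
        return pd.Timestamp(self.ds.attrs.get("t0", "2000-01-01"))

    @property
    def cell_deg(self) -> float:
        return float(self.ds.attrs.get(
            "cell_deg", float(np.diff(self.lat).mean())
        ))

    def cell_index(self, lat, lon):
        """(i, j) grid-cell indices of positions; -1 where outside the grid."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        c = self.cell_deg
        i = np.floor((lat - (self.lat[0] - c / 2)) / c).astype(int)
        j = np.floor((lon - (self.lon[0] - c / 2)) / c).astype(int)
        bad = (i < 0) | (i >= len(self.lat)) | (j < 0) | (j >= len(self.lon))
        i = np.where(bad, -1, i)
        j = np.where(bad, -1, j)
        return i, j

    def is_land(self, lat, lon):
        i, j = self.cell_index(lat, lon)
        out = np.zeros(np.shape(i), dtype=bool)
        inside = i >= 0
        out[inside] = self.mask[i[inside], j[inside]]
        return out

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds["mask"] = ds["mask"].astype("i1")  # netCDF3 has no bool
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, var_names: dict | None = None) -> "CurrentField":
        ds = xr.open_dataset(path, engine="scipy").load()
        if var_names:
            ds = ds.rename({v: k for k, v in var_names.items()})
        ds["mask"] = ds["mask"].astype(bool)
        return cls(ds)


@dataclass
class HabitatGrid:
    """Habitat cells: one grid cell of the field per site, plus a region code."""

    sites: pd.DataFrame   # columns: site, lat, lon, region

    def __post_init__(self) -> None:
        need = {"site", "lat", "lon", "region"}
        if not need.issubset(self.sites.columns):
            raise ValueError(f"habitat table must have columns {sorted(need)}")
        if self.sites["site"].duplicated().any():
            raise ValueError("site identifiers must be unique")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def site_names(self) -> list[str]:
        return list(self.sites["site"])

    @property
    def region_map(self) -> dict[str, str]:
        return dict(zip(self.sites["site"], self.sites["region"]))

    def cell_lookup(self, field: CurrentField) -> dict[tuple[int, int], str]:
        """Map (i, j) habitat cell -> site id; habitat cells must be sea."""
        out: dict[tuple[int, int], str] = {}
        i, j = field.cell_index(self.sites["lat"].values, self.sites["lon"].values)
        for k, name in enumerate(self.site_names):
            if i[k] < 0:
                raise ValueError(f"site {name!r} lies outside the field grid")
            if field.mask[i[k], j[k]]:
                raise ValueError(f"habitat cell of site {name!r} is a land cell")
            out[(int(i[k]), int(j[k]))] = name
        return out

    def to_csv(self, path) -> None:
        self.sites.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "HabitatGrid":
        return cls(pd.read_csv(path))
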