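"""Spawning phenology from accumulated degree-days and full moons.

Spawning at a site is assumed to follow the first full moon after the
cumulative thermal sum from February 1st, integral of max(T - 13, 0) dt,
exceeds 1000 degree-days; the release window opens 3 days before that full
moon and lasts 10 days at 50 particles per day (500 per site-year).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ScheduleEntry:
    site: str
    year: int
    exceedance_date: pd.Timestamp
    full_moon: pd.Timestamp
    window_start: pd.Timestamp
    window_end: pd.Timestamp          # inclusive
    particles_per_day: int = 50

    @property
    def n_days(self) -> int:
        return (self.window_end - self.window_start).days + 1

    @property
    def total_particles(self) -> int:
        return self.n_days * self.particles_per_day

    def release_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.window_start, self.window_end, freq="D")


def estimate_spawning(
    sst: pd.Series,
    moons: pd.DatetimeIndex,
    year: int,
    site: str = "",
    t_base: float = 13.0,
    start_month_day: tuple[int, int] = (2, 1),
    threshold: float = 1000.0,
    offset_days: int = 3,
    window_days: int = 10,
    particles_per_day: int = 50,
) -> ScheduleEntry | None:
    """Schedule entry for one site-year, or None when the thermal threshold
    is never reached that year (a no-spawning year, reported not fatal).

    ``sst`` is a daily series indexed by date; it must cover February 1st of
    ``year`` through the exceedance date.
    """
    start = pd.Timestamp(year, *start_month_day)
    end_of_year = pd.Timestamp(year, 12, 31)
    season = sst.loc[(sst.index >= start) & (sst.index <= end_of_year)]
    if season.empty or season.index[0] != start:
        raise ValueError(
            f"SST series does not cover {start.date()} for site {site!r}"
        )
    # daily degree-day increments; cumulative sum evaluated at day ends
    inc = np.maximum(season.to_numpy(dtype=float) - t_base, 0.0)
    cum = np.cumsum(inc)
    hit = np.flatnonzero(cum >= threshold)
    if len(hit) == 0:
        return None
    exceed = season.index[hit[0]]
    moons_norm = pd.DatetimeIndex([m.normalize() for m in moons])
    before = moons_norm[moons_norm <= exceed]
    if len(before) == 0:
        raise ValueError(
            f"no full moon on or before exceedance {exceed.date()} for "
            f"site {site!r}"
        )
    moon = before[-1]
    w0 = moon - pd.Timedelta(days=offset_days)
    w1 = w0 + pd.Timedelta(days=window_days - 1)
    return ScheduleEntry(site, year, exceed, moon, w0, w1, particles_per_day)


def build_schedule(
    sst: pd.DataFrame, moons: pd.DatetimeIndex, years, **kwargs
) -> tuple[list[ScheduleEntry], list[tuple[str, int]]]:
    """Schedules for every site column of ``sst`` over the given years.

    Returns (entries, no_spawning) where no_spawning lists (site, year)
    combinations that never reached the thermal threshold.
    """
    entries: list[ScheduleEntry] = []
    skipped: list[tuple[str, int]] = []
    for year in years:
        for site in sst.columns:
            e = estimate_spawning(sst[site], moons, year, site=site, **kwargs)
            if e is None:
                skipped.append((site, year))
            else:
                entries.append(e)
    return entries, skipped


def schedule_frame(entries: list[ScheduleEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.site, e.year, e.exceedance_date.date(), e.full_moon.date(),
             e.window_start.date(), e.window_end.date(), e.particles_per_day,
             e.total_particles)
            for e in entries
        ],
        columns=["site", "year", "exceedance", "full_moon", "window_start",
                 "window_end", "particles_per_day", "total_particles"],
    )
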