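"""Spawning phenology, Lagrangian tracking physics, and connectivity algebra."""
from datetime import date

import numpy as np
import pandas as pd
import pytest

from conftest import habitat_of, uniform_field
from coralconnect.dispersal import (
    ConnectivityMatrix, ScheduleEntry, advect, aggregate_regions,
    average_years, build_connectivity, build_schedule, conservation_check,
    estimate_spawning, iterate_generations,
)
from coralconnect.dispersal.tracking import M_PER_DEG
from coralconnect.synthetic import generate_moon_table


def year_series(year, temp):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31")
    if np.isscalar(temp):
        return pd.Series(float(temp), index=idx)
    return pd.Series(temp, index=idx)


MOONS = generate_moon_table(date(2001, 1, 1), date(2002, 2, 1), date(2001, 1, 9))


class TestPhenology:
    def test_constant_23c_exceeds_after_100_days(self):
        # 10 degree-days per day: the cumulative sum reaches 1000 at the end
        # of the 100th accumulation day (Feb 1 + 99 days)
        e = estimate_spawning(year_series(2001, 23.0), MOONS, 2001, site="X")
        assert (e.exceedance_date
                - pd.Timestamp(2001, 2, 1)).days == 99

    def test_cold_year_reports_no_spawning(self):
        assert estimate_spawning(year_series(2001, 12.5), MOONS, 2001) is None

    def test_window_geometry_and_particle_budget(self):
        e = estimate_spawning(year_series(2001, 23.0), MOONS, 2001)
        assert e.window_start == e.full_moon - pd.Timedelta(days=3)
        assert e.n_days == 10
        assert e.total_particles == 500
        assert e.full_moon <= e.exceedance_date

    def test_sinusoidal_sst_matches_brute_force_accumulation(self):
        idx = pd.date_range("2001-01-01", "2001-12-31")
        doy = idx.dayofyear.to_numpy()
        temps = 21.0 + 5.0 * np.sin(2 * np.pi * (doy - 220) / 365.25)
        s = pd.Series(temps, index=idx)
        e = estimate_spawning(s, MOONS, 2001, site="S")
        # independent brute-force daily accumulation
        cum, day = 0.0, pd.Timestamp(2001, 2, 1)
        while True:
            cum += max(s[day] - 13.0, 0.0)
            if cum >= 1000.0:
                break
            day += pd.Timedelta(days=1)
        assert e.exceedance_date == day
        moon = max(m.normalize() for m in MOONS if m.normalize() <= day)
        assert e.window_start == moon - pd.Timedelta(days=3)

    def test_chosen_moon_is_latest_not_after_exceedance(self):
        e = estimate_spawning(year_series(2001, 30.0), MOONS, 2001)
        later = [m for m in MOONS
                 if e.full_moon < m.normalize() <= e.exceedance_date]
        assert later == []

    def test_missing_coverage_rejected(self):
        idx = pd.date_range("2001-03-01", "2001-12-31")
        with pytest.raises(ValueError, match="cover"):
            estimate_spawning(pd.Series(25.0, index=idx), MOONS, 2001)

    def test_build_schedule_collects_no_spawning_years(self):
        sst = pd.DataFrame({"warm": year_series(2001, 25.0),
                            "cold": year_series(2001, 10.0)})
        entries, skipped = build_schedule(sst, MOONS, [2001])
        assert [e.site for e in entries] == ["warm"]
        assert skipped == [("cold", 2001)]


def release(site, day, n=10, year=2001):
    d = pd.Timestamp(day)
    return ScheduleEntry(site, year, d, d, d, d, n)


class TestTracking:
    def test_zero_field_self_settlement_at_competency(self):
        f = uniform_field(0.0, 0.0)
        hab = habitat_of([("A", 29.6, 130.0, "r"), ("B", 30.4, 130.0, "r")])
        fates = advect(f, [release("A", "2001-01-10")], hab, dt_hours=2)
        assert len(fates) == 10
        assert all(x.outcome == "settled" and x.dest == "A" for x in fates)
        assert all(x.age_days == pytest.approx(3.0) for x in fates)

    def test_uniform_eastward_closed_form(self):
        f = uniform_field(u=0.2, lat=(29.0, 31.0), lon=(120.0, 135.0),
                          n_days=40)
        hab = habitat_of([("S", 30.0, 121.0, "r")])
        x = advect(f, [release("S", "2001-01-02", n=1)], hab,
                   pld_max=20, competency_min=30, dt_hours=2)[0]
        expect = 121.0 + 0.2 * 20 * 86400 / (M_PER_DEG * np.cos(np.radians(30.0)))
        assert x.outcome == "expired"
        assert abs(x.final_lon - expect) / (expect - 121.0) < 1e-3
        assert x.final_lat == pytest.approx(30.0, abs=1e-6)

    def test_solid_body_rotation_returns_to_start(self):
        import xarray as xr

        from coralconnect.dispersal import CurrentField

        lat = np.arange(-2 + 1 / 24, 2, 1 / 12)
        lon = np.arange(128 + 1 / 24, 132, 1 / 12)
        LON, LAT = np.meshgrid(lon, lat)
        period_days = 10.0
        omega = 2 * np.pi / (period_days * 86400)
        xm = (LON - 130.0) * M_PER_DEG * np.cos(np.radians(LAT))
        ym = LAT * M_PER_DEG
        time = np.arange(0.0, 30.0, 1.0)
        u = np.broadcast_to(-omega * ym, (len(time),) + ym.shape)
        v = np.broadcast_to(omega * xm, (len(time),) + xm.shape)
        ds = xr.Dataset(
            {"u": (("time", "lat", "lon"), u.astype(np.float32)),
             "v": (("time", "lat", "lon"), v.astype(np.float32)),
             "mask": (("lat", "lon"), np.zeros(LAT.shape, bool))},
            coords={"time": time, "lat": lat, "lon": lon},
            attrs={"t0": "2001-01-01", "cell_deg": 1 / 12})
        f = CurrentField(ds)
        hab = habitat_of([("C", 0.5, 130.0, "r")])
        x = advect(f, [release("C", "2001-01-01", n=1)], hab,
                   pld_max=period_days, competency_min=99, dt_hours=1)[0]
        cell = 1 / 12
        assert abs(x.final_lat - 0.5) < cell
        assert abs(x.final_lon - 130.0) < cell

    def test_exit_and_conservation(self):
        f = uniform_field(u=1.0, lat=(29.0, 31.0), lon=(129.0, 131.0),
                          n_days=50)
        hab = habitat_of([("S", 30.0, 130.9, "r")])
        fates = advect(f, [release("S", "2001-01-02", n=7)], hab,
                       competency_min=99, dt_hours=2)
        assert all(x.outcome == "exited" for x in fates)
        conservation_check(fates, {"S": 7})

    def test_no_flux_coast_keeps_particles_at_sea(self):
        def wall(LAT, LON):
            return LON > 130.5
        f = uniform_field(u=0.5, mask_fn=wall, n_days=60)
        hab = habitat_of([("S", 30.1, 130.1, "r")])
        fates = advect(f, [release("S", "2001-01-02", n=3)], hab,
                       pld_max=10, competency_min=99, dt_hours=2)
        assert all(x.outcome == "expired" for x in fates)
        assert all(not f.is_land(np.array([x.final_lat]),
                                 np.array([x.final_lon]))[0] for x in fates)

    @pytest.mark.parametrize("dt", [0.0, -2.0, 30.0])
    def test_bad_dt_rejected(self, dt):
        f = uniform_field()
        hab = habitat_of([("A", 29.6, 130.0, "r")])
        with pytest.raises(ValueError, match="dt"):
            advect(f, [release("A", "2001-01-10")], hab, dt_hours=dt)


class TestConnectivityAlgebra:
    def test_zero_velocity_identity_pattern(self):
        f = uniform_field(0.0, 0.0)
        hab = habitat_of([("A", 29.6, 130.0, "r"), ("B", 30.4, 130.2, "r")])
        entries = [release("A", "2001-01-10"), release("B", "2001-01-10")]
        fates = advect(f, entries, hab, dt_hours=2)
        C = build_connectivity(fates, hab.site_names,
                               {"A": 10, "B": 10}, year=2001)
        assert np.allclose(C.values, np.eye(2))

    def test_hand_built_ratio(self):
        fates = []
        for k in range(500):
            fates.append(
                type("F", (), {"source": "i", "dest": "j",
                               "outcome": "settled" if k < 250 else "expired"})
            )
        C = build_connectivity(fates, ["i", "j"], {"i": 500, "j": 1})
        assert C.values[0, 1] == pytest.approx(0.5)

    def test_zero_release_row_warns(self):
        with pytest.warns(UserWarning, match="released no"):
            C = build_connectivity([], ["a", "b"], {"a": 0, "b": 0})
        assert (C.values == 0).all()

    def test_average_years(self):
        rng = np.random.default_rng(2)
        mats = [ConnectivityMatrix(["a", "b"], rng.random((2, 2)) / 2)
                for _ in range(24)]
        mean = average_years(mats)
        assert np.allclose(mean.values,
                           np.mean([m.values for m in mats], axis=0))
        single = average_years([mats[0]])
        assert np.allclose(single.values, mats[0].values)
        half = average_years([mats[0],
                              ConnectivityMatrix(["a", "b"], np.zeros((2, 2)))])
        assert np.allclose(half.values, mats[0].values / 2)
        with pytest.raises(ValueError):
            average_years([])

    def test_iterate_identity_fixed_point(self):
        C = ConnectivityMatrix(list("abc"), np.eye(3))
        A, trace = iterate_generations(C, n_gen=50, tol=1e-12)
        assert np.allclose(A.values, np.eye(3))
        assert trace[0] == 0.0

    def test_one_way_chain_reaches_end_in_two_generations(self):
        C = ConnectivityMatrix(
            list("abc"),
            np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], float))
        A, _ = iterate_generations(C, n_gen=3)
        assert A.values[0, 2] == pytest.approx(1.0)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(3)
        C = ConnectivityMatrix([f"s{i}" for i in range(5)],
                               rng.random((5, 5)) / 5)
        prev = C.values.copy()
        for g in (2, 5, 20, 200):
            A, _ = iterate_generations(C, n_gen=g)
            assert (A.values >= prev - 1e-12).all()
            assert (A.values <= 1 + 1e-9).all()
            prev = A.values

    def test_matches_brute_force_reachability_support(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        vals = rng.random((5, 5)) / 5
        vals[vals < 0.1] = 0.0
        C = ConnectivityMatrix([f"s{i}" for i in range(5)], vals)
        A, _ = iterate_generations(C, n_gen=1000, tol=0.0)
        # off-diagonal support of the stabilised matrix = graph reachability
        g = nx.from_numpy_array(vals, create_using=nx.DiGraph)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                assert (A.values[i, j] > 1e-9) == nx.has_path(g, i, j)

    def test_brute_force_recursion_equivalence(self):
        """The closed implementation equals a plain re-implementation of the
        recursion run to convergence."""
        rng = np.random.default_rng(5)
        vals = rng.random((6, 6)) / 6
        C = ConnectivityMatrix([f"s{i}" for i in range(6)], vals)
        A, _ = iterate_generations(C, n_gen=500, tol=0.0)
        rows = vals.sum(axis=1, keepdims=True)
        chat = np.where(rows > 0, vals / rows, 0.0)
        B = vals.copy()
        for _ in range(499):
            step = np.clip(B @ chat, 0, 1)
            B = np.clip(B + step - B * step, 0, 1)
        assert np.allclose(A.values, B, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix(["a"], np.zeros((1, 2)))

    def test_aggregate_regions(self):
        C = ConnectivityMatrix(
            ["a1", "a2", "b1", "b2"],
            np.array([
                [0.1, 0.2, 0.3, 0.0],
                [0.0, 0.1, 0.1, 0.1],
                [0.0, 0.0, 0.2, 0.2],
                [0.0, 0.0, 0.0, 0.4],
            ]))
        regions = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        R = aggregate_regions(C, regions)
        # hand-summed blocks, then mean over source sites
        assert R.values[0, 0] == pytest.approx(((0.1 + 0.2) + (0.0 + 0.1)) / 2)
        assert R.values[0, 1] == pytest.approx(((0.3 + 0.0) + (0.1 + 0.1)) / 2)
        assert R.values[1, 0] == pytest.approx(0.0)
        assert R.values[1, 1] == pytest.approx(((0.2 + 0.2) + (0.0 + 0.4)) / 2)

    def test_aggregate_single_region_mean_row_sum(self):
        C = ConnectivityMatrix(["a", "b"],
                               np.array([[0.2, 0.3], [0.1, 0.0]]))
        R = aggregate_regions(C, {"a": "R", "b": "R"})
        assert R.values[0, 0] == pytest.approx((0.5 + 0.1) / 2)

    def test_unmapped_site_rejected(self):
        C = ConnectivityMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="without a region"):
            aggregate_regions(C, {"a": "R"})
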