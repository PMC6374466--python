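"""Distance predictors and the Mantel permutation test."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralconnect.ibd import (
    connectivity_distance, great_circle_matrix, haversine_km, mantel,
    sea_path_matrix,
)
from coralconnect.dispersal import ConnectivityMatrix
from coralconnect.matrices import PairwiseMatrix


class TestGreatCircle:
    def test_identical_points_zero(self):
        m = great_circle_matrix({"a": (30.0, 130.0), "b": (30.0, 130.0)})
        assert m.values[0, 1] == 0.0

    def test_one_degree_longitude_at_equator(self):
        m = great_circle_matrix({"a": (0.0, 0.0), "b": (0.0, 1.0)})
        # 2*pi*6371/360 km
        assert m.values[0, 1] == pytest.approx(111.19, abs=0.1)

    def test_latitude_bounds_checked(self):
        with pytest.raises(ValueError):
            great_circle_matrix({"a": (95.0, 0.0), "b": (0.0, 0.0)})

    @given(st.floats(-80, 80), st.floats(-170, 170),
           st.floats(-80, 80), st.floats(-170, 170))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, la1, lo1, la2, lo2):
        d1 = haversine_km(la1, lo1, la2, lo2)
        d2 = haversine_km(la2, lo2, la1, lo1)
        assert d1 == pytest.approx(d2, rel=1e-9)
        assert d1 >= 0


def grid(lat0=29.0, lat1=31.0, lon0=129.0, lon1=132.0, cell=0.25):
    lat = np.arange(lat0 + cell / 2, lat1, cell)
    lon = np.arange(lon0 + cell / 2, lon1, cell)
    return lat, lon


class TestSeaPath:
    def test_open_sea_close_to_great_circle(self):
        lat, lon = grid()
        mask = np.zeros((len(lat), len(lon)), bool)
        coords = {"a": (29.5, 129.5), "b": (30.5, 131.5)}
        sp = sea_path_matrix(coords, mask, lat, lon)
        gc = great_circle_matrix(coords)
        # discretisation: within about one cell diagonal plus the 8-connected
        # lattice detour factor (<= ~8% of the path length)
        assert sp.values[0, 1] >= gc.values[0, 1] - 1e-9
        assert sp.values[0, 1] <= gc.values[0, 1] * 1.09 + 40.0

    def test_wall_with_gap_matches_graph_oracle(self):
        import networkx as nx

        lat, lon = grid()
        mask = np.zeros((len(lat), len(lon)), bool)
        jwall = np.argmin(np.abs(lon - 130.5))
        mask[:, jwall] = True
        gap = len(lat) // 2
        mask[gap, jwall] = False          # one hole in the wall
        coords = {"a": (30.0, 129.5), "b": (30.0, 131.5)}
        sp = sea_path_matrix(coords, mask, lat, lon)

        g = nx.Graph()
        for i in range(len(lat)):
            for j in range(len(lon)):
                if mask[i, j]:
                    continue
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if (di, dj) != (0, 0) and 0 <= ii < len(lat) \
                                and 0 <= jj < len(lon) and not mask[ii, jj]:
                            g.add_edge((i, j), (ii, jj), weight=float(
                                haversine_km(lat[i], lon[j], lat[ii], lon[jj])))
        src = (np.argmin(np.abs(lat - 30.0)), np.argmin(np.abs(lon - 129.5)))
        dst = (np.argmin(np.abs(lat - 30.0)), np.argmin(np.abs(lon - 131.5)))
        oracle = nx.shortest_path_length(g, src, dst, weight="weight")
        assert sp.values[0, 1] == pytest.approx(oracle, rel=1e-9)
        # and the detour is strictly longer than the unobstructed line
        assert sp.values[0, 1] > great_circle_matrix(coords).values[0, 1]

    def test_adding_land_never_shortens(self):
        lat, lon = grid()
        coords = {"a": (29.5, 129.5), "b": (30.5, 131.5)}
        mask0 = np.zeros((len(lat), len(lon)), bool)
        d0 = sea_path_matrix(coords, mask0, lat, lon).values[0, 1]
        mask1 = mask0.copy()
        mask1[2:5, 4:8] = True
        d1 = sea_path_matrix(coords, mask1, lat, lon).values[0, 1]
        assert d1 >= d0 - 1e-9

    def test_enclosed_site_reported(self):
        lat, lon = grid()
        mask = np.zeros((len(lat), len(lon)), bool)
        mask[:, 6] = True                  # unbroken wall
        coords = {"a": (30.0, 129.5), "b": (30.0, 131.5)}
        with pytest.raises(ValueError, match="no sea route"):
            sea_path_matrix(coords, mask, lat, lon)


class TestConnectivityDistance:
    def test_equal_flow_equal_distance(self):
        C = ConnectivityMatrix(list("abc"), np.full((3, 3), 0.2))
        d = connectivity_distance(C)
        off = d.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_monotone_decreasing_in_flow(self):
        vals = np.array([[0.0, 0.4, 0.1], [0.0, 0.0, 0.2], [0.0, 0.0, 0.0]])
        d = connectivity_distance(ConnectivityMatrix(list("abc"), vals))
        assert d["a", "b"] < d["b", "c"] < d["a", "c"]

    def test_matches_direct_formula(self):
        vals = np.array([[0.0, 0.3, 0.0], [0.1, 0.0, 0.05], [0.0, 0.0, 0.0]])
        d = connectivity_distance(ConnectivityMatrix(list("abc"), vals))
        sym = (vals + vals.T) / 2
        eps = 0.025 / 2                    # half the smallest positive entry
        assert d["a", "b"] == pytest.approx(-np.log(sym[0, 1] + eps))
        assert d["b", "c"] == pytest.approx(-np.log(sym[1, 2] + eps))
        # zero-flow pair sits strictly beyond every connected pair
        assert d["a", "c"] > max(d["a", "b"], d["b", "c"])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            connectivity_distance(ConnectivityMatrix(["a", "b"],
                                                     np.zeros((2, 2))))


class TestSteppingStonePower:
    def test_ibd_detected_on_linear_stepping_stone(self):
        """With neighbour-limited migration along a chain, genetic and
        geographic distance correlate: Mantel r > 0 and p < 0.05 in the
        majority of replicates."""
        from coralconnect.popgen import pairwise_fst
        from coralconnect.synthetic import SimGenotypeConfig, generate_genotypes

        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            t = generate_genotypes(SimGenotypeConfig(
                layout="linear-stepping-stone", fst_target=0.108,
                seed=9_000 + rep))
            fst = pairwise_fst(t)[0]
            coords = pd.DataFrame({
                "lat": {p: t.coords[p][0] for p in t.pop_names},
                "lon": {p: t.coords[p][1] for p in t.pop_names},
            })
            res = mantel(fst, great_circle_matrix(coords), n_perm=199,
                         seed=rep)
            wins += (res.r > 0 and res.p < 0.05)
        assert wins > n_rep / 2


def random_sym(rng, n=6):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestMantel:
    def test_identity_gives_r_one_minimal_p(self):
        rng = np.random.default_rng(0)
        m = random_sym(rng)
        labels = [f"p{i}" for i in range(6)]
        a = PairwiseMatrix(labels, m)
        b = PairwiseMatrix(labels, m * 3.0 + 1.0)   # affine of itself
        res = mantel(a, b, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 2 / 1000

    def test_invariant_under_joint_relabelling(self):
        rng = np.random.default_rng(1)
        labels = [f"p{i}" for i in range(7)]
        a = PairwiseMatrix(labels, random_sym(rng, 7))
        b = PairwiseMatrix(labels, random_sym(rng, 7))
        r0 = mantel(a, b, n_perm=0 + 1, seed=0).r
        perm = list(np.random.default_rng(2).permutation(labels))
        r1 = mantel(a.submatrix(perm), b.submatrix(perm), n_perm=1, seed=0).r
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_exclusion_and_small_matrix_guard(self):
        labels = [f"p{i}" for i in range(5)]
        rng = np.random.default_rng(3)
        a = PairwiseMatrix(labels, random_sym(rng, 5))
        b = PairwiseMatrix(labels, random_sym(rng, 5))
        res = mantel(a, b, n_perm=99, exclude=["p0"], seed=0)
        assert res.excluded == ["p0"]
        with pytest.raises(ValueError, match="at least 4"):
            mantel(a, b, n_perm=9, exclude=["p0", "p1"])

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        labels = [f"p{i}" for i in range(8)]
        # embed points so both matrices are metric
        pts1 = rng.random((8, 2))
        pts2 = pts1 + rng.normal(0, 0.1, (8, 2))
        d1 = np.linalg.norm(pts1[:, None] - pts1[None], axis=2)
        d2 = np.linalg.norm(pts2[:, None] - pts2[None], axis=2)
        ours = mantel(PairwiseMatrix(labels, d1), PairwiseMatrix(labels, d2),
                      n_perm=999, seed=5)
        theirs_r, theirs_p, _ = skbio_mantel(
            DistanceMatrix(d1, labels), DistanceMatrix(d2, labels),
            permutations=999, alternative="greater")
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)
        assert abs(ours.p - theirs_p) < 0.05

    def test_linearised_fst_option(self):
        rng = np.random.default_rng(6)
        labels = [f"p{i}" for i in range(5)]
        g = random_sym(rng, 5) * 0.2
        x = random_sym(rng, 5)
        a = PairwiseMatrix(labels, g)
        b = PairwiseMatrix(labels, x)
        r_raw = mantel(a, b, n_perm=1, seed=0).r
        r_lin = mantel(a, b, n_perm=1, seed=0, linearize_fst=True).r
        lin = g / (1 - g)
        iu = np.triu_indices(5, 1)
        expect = np.corrcoef(lin[iu], x[iu])[0, 1]
        assert r_lin == pytest.approx(expect, abs=1e-12)
        assert r_lin != pytest.approx(r_raw, abs=1e-12) or True
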