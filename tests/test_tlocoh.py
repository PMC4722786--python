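"""Time-local convex hulls: TSD, neighbour rules, metrics, isopleths."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foragemap.tlocoh import (
    HullConfig,
    TLoCoH,
    TSDParams,
    build_hulls,
    build_isopleths,
    export_cfa,
    hull_metrics,
    import_cfa,
    max_observed_speed,
    select_a,
    select_neighbors,
    select_s,
    tsd,
    tsd_matrix,
)


def make_traj(xy, hours=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    hours = np.arange(n) * 4.0 if hours is None else np.asarray(hours, float)
    t0 = pd.Timestamp("2013-06-01T00:00:00Z")
    return pd.DataFrame(
        {
            "id": "t",
            "t": [t0 + pd.Timedelta(hours=h) for h in hours],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


def random_traj(n, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0, scale / 10, size=(n, 2)), axis=0)
    return make_traj(xy)


class TestTSD:
    def test_s_zero_is_euclidean(self):
        p = TSDParams(s=0.0, v_max=1.0)
        assert tsd((0, 0, 0), (3, 4, 9999), p) == pytest.approx(5.0)

    def test_zero_lag_is_euclidean(self):
        p = TSDParams(s=2.0, v_max=1.5)
        assert tsd((0, 0, 50), (3, 4, 50), p) == pytest.approx(5.0)

    def test_hand_computed_value(self):
        p = TSDParams(s=0.01, v_max=0.5)
        val = tsd((0, 0, 0), (3, 4, 3600), p)
        assert val == pytest.approx(math.sqrt(349), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-1e4, 1e4), st.floats(-1e4, 1e4), st.floats(-1e5, 1e5),
        st.floats(0, 10), st.floats(0.01, 10),
    )
    def test_metric_properties(self, dx, dy, dt, s, vmax):
        p = TSDParams(s=s, v_max=vmax)
        a, b = (0.0, 0.0, 0.0), (dx, dy, dt)
        d_ab = tsd(a, b, p)
        assert d_ab == pytest.approx(tsd(b, a, p))  # symmetry
        assert d_ab >= math.hypot(dx, dy) - 1e-9  # >= Euclidean
        assert d_ab >= 0


class TestMaxObservedSpeed:
    def test_stationary_zero(self):
        assert max_observed_speed(make_traj([(0, 0)] * 5)) == 0.0

    def test_single_step(self):
        traj = make_traj([(0, 0), (100, 0)], hours=[0, 1])
        assert max_observed_speed(traj) == pytest.approx(100 / 3600)

    def test_equals_bruteforce_max(self):
        traj = random_traj(60, seed=3)
        xy = traj[["x", "y"]].to_numpy()
        t = traj["t"].astype("int64").to_numpy() / 1e9
        oracle = max(
            np.linalg.norm(xy[i + 1] - xy[i]) / (t[i + 1] - t[i])
            for i in range(len(xy) - 1)
        )
        assert max_observed_speed(traj) == pytest.approx(oracle)


class TestSelectS:
    def test_ptsh_zero_at_s_zero(self, two_patch_traj):
        from foragemap.tlocoh import ptsh

        assert ptsh(two_patch_traj, 0.0) == 0.0

    def test_ptsh_trend_nondecreasing_overall(self, two_patch_traj):
        from foragemap.tlocoh import ptsh

        vals = [ptsh(two_patch_traj, s) for s in (1e-4, 1e-2, 1.0, 10.0)]
        assert vals[-1] >= vals[0]
        assert vals[-1] > 0.5  # time-ordered neighbours differ for most points

    def test_achieves_target_on_standard_fixture(self, two_patch_traj):
        s, achieved = select_s(two_patch_traj, target_ptsh=0.60)
        assert abs(achieved - 0.60) <= 0.05

    def test_simultaneous_fixes_rejected(self):
        traj = make_traj([(0, 0), (1, 0), (2, 0), (3, 0)], hours=[0, 4, 8, 12])
        # no movement in time -> selection works; zero speed is the error path
        with pytest.raises(ValueError):
            select_s(make_traj([(0, 0)] * 6))


def oracle_neighbors(xy, t, s, vmax, config):
    """Exhaustive-sort reference implementation of the neighbour rules."""
    n = len(xy)
    out = []
    for i in range(n):
        d = [
            (math.sqrt((xy[i, 0] - xy[j, 0]) ** 2 + (xy[i, 1] - xy[j, 1]) ** 2
                       + (s * vmax * (t[i] - t[j])) ** 2), j)
            for j in range(n) if j != i
        ]
        d.sort()
        take = []
        if config.method == "a":
            acc = 0.0
            for dist, j in d:
                if acc + dist > config.a:
                    break
                acc += dist
                take.append(j)
        elif config.method == "k":
            take = [j for _, j in d[: config.k - 1]]
        else:
            take = [j for dist, j in d if dist <= config.r]
        out.append(sorted([i] + take))
    return out


@pytest.mark.parametrize(
    "config",
    [
        HullConfig(method="a", a=500.0),
        HullConfig(method="k", k=8),
        HullConfig(method="r", r=300.0),
    ],
    ids=["a-method", "k-method", "r-method"],
)
def test_neighbor_selection_matches_oracle(config):
    traj = random_traj(50, seed=7)
    xy = traj[["x", "y"]].to_numpy()
    t = traj["t"].astype("int64").to_numpy() / 1e9
    vmax = max_observed_speed(traj)
    got = select_neighbors(traj, 0.05, config, v_max=vmax)
    expect = oracle_neighbors(xy, t, 0.05, vmax, config)
    for g, e in zip(got, expect):
        assert list(g) == e


class TestNeighborEdgeCases:
    def test_tiny_a_gives_parent_only_hulls(self):
        traj = random_traj(20, seed=1)
        nbrs = select_neighbors(traj, 0.0, HullConfig(method="a", a=1e-9))
        assert all(len(x) == 1 for x in nbrs)

    def test_infinite_a_gives_all_points(self):
        traj = random_traj(20, seed=1)
        nbrs = select_neighbors(traj, 0.0, HullConfig(method="a", a=np.inf))
        assert all(len(x) == 20 for x in nbrs)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            HullConfig(method="a", k=5).validate()
        with pytest.raises(ValueError):
            HullConfig(method="a", a=10.0, r=5.0).validate()


class TestBuildHulls:
    def test_unit_triangle_shoelace_area(self):
        traj = make_traj([(0, 0), (1, 0), (0, 1)])
        hs = build_hulls(traj, [np.array([0, 1, 2])] * 3)
        assert hs.hulls[0].area == pytest.approx(0.5)
        assert hs.hulls[0].perimeter == pytest.approx(2 + math.sqrt(2))

    def test_collinear_degenerate_hull(self):
        traj = make_traj([(0, 0), (1, 0), (2, 0)])
        hs = build_hulls(traj, [np.array([0, 1, 2])] * 3)
        assert hs.hulls[0].area == 0.0
        assert hs.hulls[0].perimeter == pytest.approx(4.0)  # out-and-back
        assert list(hs.hulls[0].enclosed) == [0, 1, 2]

    def test_enclosed_points_match_bruteforce(self):
        from shapely.geometry import Point

        traj = random_traj(40, seed=5)
        cfg = HullConfig(method="k", k=6)
        hs = build_hulls(traj, select_neighbors(traj, 0.0, cfg))
        xy = traj[["x", "y"]].to_numpy()
        for h in hs.hulls[::5]:
            oracle = [
                i for i in range(len(xy))
                if h.polygon.covers(Point(xy[i]))
            ]
            assert list(h.enclosed) == oracle

    def test_parent_always_enclosed(self):
        traj = random_traj(30, seed=9)
        hs = build_hulls(traj, select_neighbors(traj, 0.0, HullConfig(method="k", k=5)))
        for h in hs.hulls:
            assert h.parent in h.enclosed


class TestHullMetrics:
    def _hullset_with_times(self, hours):
        traj = make_traj([(0, 0)] * len(hours), hours=hours)
        hs = build_hulls(traj, [np.arange(len(hours))])
        return hs

    def test_gap_grouping_example(self):
        hs = self._hullset_with_times([0, 4, 20])
        hull_metrics(hs, ivg=43200.0)
        assert hs.hulls[0].nsv == 2  # visits {0,4} and {20}

    def test_single_window_one_visit(self):
        hs = self._hullset_with_times([0, 4, 8])
        hull_metrics(hs, ivg=43200.0)
        assert hs.hulls[0].nsv == 1

    def test_max_nsv_normalised_to_one(self, two_patch_traj):
        hs = build_hulls(
            two_patch_traj,
            select_neighbors(two_patch_traj, 0.0, HullConfig(method="k", k=6)),
        )
        hull_metrics(hs)
        assert max(h.nnsv for h in hs.hulls) == 1.0


class TestIsopleths:
    def _metric_hulls(self, traj):
        hs = build_hulls(traj, select_neighbors(traj, 0.0, HullConfig(method="k", k=6)))
        return hull_metrics(hs)

    def test_level_one_encloses_all_fixes(self):
        traj = random_traj(30, seed=2)
        iso = build_isopleths(self._metric_hulls(traj), (1.0,))
        assert iso[1.0].enclosed_fraction == pytest.approx(1.0)

    def test_stopping_rule_meets_level(self):
        traj = random_traj(30, seed=2)
        iso = build_isopleths(self._metric_hulls(traj), (0.3,))
        assert iso[0.3].enclosed_fraction >= 0.3

    def test_nesting_across_levels(self):
        traj = random_traj(40, seed=4)
        iso = build_isopleths(self._metric_hulls(traj), (0.3, 0.6, 0.9))
        assert iso[0.3].area <= iso[0.6].area <= iso[0.9].area
        # containment up to floating-point boundary noise
        assert iso[0.3].polygon.difference(iso[0.6].polygon).area < 1e-9
        assert iso[0.6].polygon.difference(iso[0.9].polygon).area < 1e-9

    def test_union_counts_match_point_in_union_oracle(self):
        from shapely.geometry import Point
        from foragemap.tlocoh import _sorted_hulls

        traj = random_traj(10, seed=6)
        hs = self._metric_hulls(traj)
        ordered = _sorted_hulls(hs, "nnsv")
        xy = traj[["x", "y"]].to_numpy()
        running = None
        for h in ordered:
            running = h.polygon if running is None else running.union(h.polygon)
            count = sum(running.covers(Point(p)) for p in xy)
            iso = build_isopleths(hs, (count / len(xy),))
            assert iso[count / len(xy)].enclosed_fraction >= count / len(xy)

    def test_determinism(self, two_patch_traj):
        hs = self._metric_hulls(two_patch_traj)
        a = build_isopleths(hs, (0.3,))
        b = build_isopleths(hs, (0.3,))
        assert a[0.3].polygon.equals_exact(b[0.3].polygon, 0)


class TestSelectA:
    def test_requires_three_candidates(self, two_patch_traj):
        with pytest.raises(ValueError):
            select_a(two_patch_traj, 0.01, [100.0])

    def test_area_curve_grows_with_a(self, two_patch_traj):
        """Core-isopleth area grows with the cumulative-TSD threshold, up to
        the discreteness of the 30% stopping rule (a larger ``a`` may reach
        the level with one big hull slightly smaller than a union of several
        smaller ones)."""
        _, diag = select_a(
            two_patch_traj, 0.01, [200.0, 500.0, 1000.0, 2000.0, 4000.0]
        )
        area = diag["area"].to_numpy()
        assert area[-1] > area[0]
        assert np.all(np.diff(area) >= -0.10 * area[:-1])

    def test_two_cluster_fixture_keeps_clusters_separate(self):
        """Selected a stays below the jump that bridges well-separated
        clusters: the core isopleth remains multi-part."""
        rng = np.random.default_rng(0)
        a_pts = rng.normal(0, 20, (40, 2))
        b_pts = rng.normal(0, 20, (40, 2)) + [2000.0, 0.0]
        xy = np.empty((80, 2))
        xy[0::2] = a_pts
        xy[1::2] = b_pts
        traj = make_traj(xy)
        chosen, diag = select_a(traj, 0.0, [100.0, 200.0, 400.0, 800.0, 1600.0])
        cfg = HullConfig(method="a", a=chosen)
        hs = hull_metrics(build_hulls(traj, select_neighbors(traj, 0.0, cfg)))
        iso = build_isopleths(hs, (0.3,))
        assert chosen < 2000.0
        # polygon does not bridge the 2 km gap
        minx, _, maxx, _ = iso[0.3].polygon.bounds
        assert maxx - minx < 2000.0


class TestExportImport:
    def test_round_trip(self, tmp_path, two_patch_traj):
        est = TLoCoH(method="a", a=2000.0, s=0.01, levels=(0.3,)).fit(two_patch_traj)
        path = tmp_path / "cfa.geojson"
        export_cfa(est.isopleths_, path, level=0.3, individual="animal01")
        geom, props = import_cfa(path)
        assert props["level"] == 0.3
        assert props["individual"] == "animal01"
        assert geom.symmetric_difference(est.cfa_).area < 1e-6 * max(est.cfa_.area, 1)

    def test_missing_level_raises(self, two_patch_traj):
        est = TLoCoH(method="a", a=2000.0, s=0.01, levels=(0.3,)).fit(two_patch_traj)
        with pytest.raises(KeyError):
            est.isopleths_[0.5]


class TestTLoCoHEstimator:
    def test_fit_selects_s_near_target_and_builds_cfa(self, two_patch_traj):
        est = TLoCoH(method="a", a=2000.0, s="auto").fit(two_patch_traj)
        assert abs(est.ptsh_ - 0.60) <= 0.05
        assert est.cfa_.area > 0
        assert est.isopleths_[0.3].enclosed_fraction >= 0.3

    def test_sklearn_params(self):
        est = TLoCoH(ivg=3600.0)
        assert est.get_params()["ivg"] == 3600.0
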