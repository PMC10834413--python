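"""Geometry predictors: fetch, boat distances, access metrics, dedup."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

from stonewort import geo
from stonewort.errors import ConfigurationError, GeometryError


def analytic_circle_fetch(radius: float, offset: float, n_bearings: int) -> float:
    """Longest chord through a point at distance ``offset`` from the center.

    A chord whose direction makes angle g with the point->center direction
    has length 2 sqrt(R^2 - offset^2 sin^2 g); maximize over the discrete
    undirected bearings.
    """
    thetas = np.unique((np.arange(n_bearings) * 360.0 / n_bearings) % 180.0)
    # the point sits on the +x axis; bearing t (from north) has direction
    # (sin t, cos t); the angle to the center direction (-1, 0) is arbitrary
    # but sin^2 of it is sin^2(t - 90deg) = cos^2 t
    best = 0.0
    for t in np.radians(thetas):
        sin_g_sq = math.cos(t) ** 2
        best = max(best, 2.0 * math.sqrt(radius**2 - offset**2 * sin_g_sq))
    return best


class TestFetch:
    def test_circle_center_every_chord_is_a_diameter(self, circle_lake):
        fetch = geo.compute_fetch((0.0, 0.0), circle_lake)
        assert fetch == pytest.approx(1000.0, rel=1e-3)

    def test_offcenter_circle_matches_chord_formula(self, circle_lake):
        offset = 300.0
        fetch = geo.compute_fetch((offset, 0.0), circle_lake, n_bearings=36)
        assert fetch == pytest.approx(
            analytic_circle_fetch(500.0, offset, 36), rel=1e-3
        )

    def test_rectangle_centroid_long_axis(self, rect_lake):
        fetch = geo.compute_fetch((1000.0, 50.0), rect_lake)
        assert fetch == pytest.approx(2000.0, rel=1e-9)

    def test_island_truncates_the_chord(self, island_lake):
        # point west of the island; the E-W chord stops at the island wall
        fetch_we = geo.compute_fetch((150.0, 300.0), island_lake, n_bearings=2)
        # bearings {0, 90}: N-S chord is 600, E-W is truncated at x=300
        assert fetch_we == pytest.approx(600.0, rel=1e-9)

    def test_rotation_invariance_at_multiples_of_bearing_step(self, island_lake):
        p = (150.0, 300.0)
        base = geo.compute_fetch(p, island_lake, n_bearings=36)
        rotated_poly = shapely.affinity.rotate(
            island_lake.polygon, 20.0, origin=(0.0, 0.0)
        )
        rotated_lake = geo.LakeGeometry("rot", rotated_poly)
        q = shapely.affinity.rotate(Point(p), 20.0, origin=(0.0, 0.0))
        assert geo.compute_fetch((q.x, q.y), rotated_lake, n_bearings=36) == (
            pytest.approx(base, rel=1e-6)
        )

    def test_bounded_between_shore_distance_and_diameter(self, island_lake, rng):
        pts = []
        while len(pts) < 10:
            cand = (rng.uniform(0, 1000), rng.uniform(0, 600))
            if island_lake.polygon.contains(Point(cand)):
                pts.append(cand)
        for p in pts:
            fetch = geo.compute_fetch(p, island_lake)
            assert fetch >= island_lake.polygon.boundary.distance(Point(p))
            assert fetch <= island_lake.diameter

    def test_point_outside_polygon_rejected(self, circle_lake):
        with pytest.raises(GeometryError):
            geo.compute_fetch((600.0, 600.0), circle_lake)


def grid_dijkstra_oracle(
    poly: Polygon, origin: tuple, target: tuple, spacing: float = 5.0
) -> float:
    """Brute-force shortest water path on a fine 8-connected grid graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as sp_dijkstra

    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx + spacing, spacing)
    ys = np.arange(miny, maxy + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    nodes = np.vstack([nodes, origin, target])
    inside = shapely.covers(poly, shapely.points(nodes))
    nodes = nodes[inside]
    from scipy.spatial import cKDTree

    # include knight-move edges: 8-connected grids alone distort the metric
    # by up to ~8%, far beyond the 1% oracle tolerance
    kd = cKDTree(nodes)
    pairs = kd.query_pairs(r=spacing * 2.4, output_type="ndarray")
    segs = shapely.linestrings(np.stack([nodes[pairs[:, 0]], nodes[pairs[:, 1]]], axis=1))
    ok = shapely.covers(poly, segs)
    pairs = pairs[ok]
    w = np.hypot(*(nodes[pairs[:, 0]] - nodes[pairs[:, 1]]).T)
    n = len(nodes)
    g = coo_matrix((w, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    io = int(np.flatnonzero(np.all(np.isclose(nodes, origin), axis=1))[0])
    it = int(np.flatnonzero(np.all(np.isclose(nodes, target), axis=1))[0])
    dist = sp_dijkstra(g + g.T, directed=False, indices=io)
    return float(dist[it])


class TestBoatDistance:
    def test_convex_lake_equals_euclidean(self, circle_lake, rng):
        net = geo.BoatNetwork(circle_lake)
        for _ in range(10):
            a = rng.uniform(-300, 300, 2)
            b = rng.uniform(-300, 300, 2)
            d = net.distance(tuple(a), tuple(b))
            assert d == pytest.approx(np.hypot(*(a - b)), rel=1e-9)

    def test_identical_points_have_zero_distance(self, island_lake):
        assert geo.boat_distance((100.0, 100.0), (100.0, 100.0), island_lake) == 0.0

    def test_route_around_island_picks_the_shorter_corner(self, island_lake):
        net = geo.BoatNetwork(island_lake)
        a, b = (250.0, 300.0), (750.0, 300.0)
        d = net.distance(a, b)
        # two candidate routes: around the south (y=200) or north (y=400) wall
        via_south = (
            math.hypot(300 - 250, 200 - 300)
            + 400.0
            + math.hypot(750 - 700, 300 - 200)
        )
        assert d == pytest.approx(via_south, rel=1e-9)
        assert d > math.hypot(500, 0)  # strictly longer than Euclidean

    def test_matches_grid_dijkstra_oracle_within_one_percent(self, island_lake):
        a, b = (250.0, 300.0), (750.0, 300.0)
        d = geo.boat_distance(a, b, island_lake)
        oracle = grid_dijkstra_oracle(island_lake.polygon, a, b, spacing=5.0)
        assert d <= oracle + 1e-9  # grid path is suboptimal
        assert abs(d - oracle) / d < 0.01

    def test_symmetry_and_triangle_inequality(self, island_lake, rng):
        net = geo.BoatNetwork(island_lake)
        pts = []
        while len(pts) < 6:
            cand = (rng.uniform(0, 1000), rng.uniform(0, 600))
            if island_lake.polygon.contains(Point(cand)):
                pts.append(cand)
        d = {}
        for i, p in enumerate(pts):
            for j, q in enumerate(pts):
                if i < j:
                    d[i, j] = d[j, i] = net.distance(p, q)
                    assert net.distance(q, p) == pytest.approx(d[i, j], rel=1e-12)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    if len({i, j, k}) == 3:
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_point_on_land_rejected(self, island_lake):
        with pytest.raises(GeometryError):
            geo.boat_distance((500.0, 300.0), (100.0, 100.0), island_lake)

    def test_disconnected_waterbodies_rejected_at_merge(self):
        from shapely.geometry import box

        with pytest.raises(GeometryError, match="not connected"):
            geo.merge_waterbodies("twin", [box(0, 0, 10, 10), box(20, 0, 30, 10)])


class TestAccesses:
    def test_single_access_distance_and_kind(self, circle_lake):
        d, kind = geo.nearest_access((0.0, 0.0), circle_lake)
        assert kind == geo.PUBLIC
        assert d == pytest.approx(500.0, rel=1e-3)

    def test_closer_private_access_wins(self):
        from shapely.geometry import box

        lake = geo.LakeGeometry(
            "sq",
            box(0, 0, 1000, 1000),
            [
                geo.Access("far-public", 1000.0, 500.0, geo.PUBLIC),
                geo.Access("near-private", 0.0, 500.0, geo.PRIVATE),
            ],
        )
        d, kind = geo.nearest_access((200.0, 500.0), lake)
        assert kind == geo.PRIVATE
        assert d == pytest.approx(200.0)

    def test_exact_tie_breaks_to_smaller_access_id(self):
        from shapely.geometry import box

        lake = geo.LakeGeometry(
            "sq",
            box(0, 0, 100, 100),
            [
                geo.Access("B", 100.0, 0.0, geo.PRIVATE),
                geo.Access("A", 0.0, 0.0, geo.PUBLIC),
            ],
        )
        # (50, 10) is equidistant from both bottom corners
        d, kind = geo.nearest_access((50.0, 10.0), lake)
        assert kind == geo.PUBLIC  # access "A" sorts first
        assert d == pytest.approx(math.hypot(50, 10))

    def test_no_access_is_a_configuration_error(self, rect_lake):
        with pytest.raises(ConfigurationError):
            geo.nearest_access((1000.0, 50.0), rect_lake)

    def test_counts_within_radius_convex(self):
        from shapely.geometry import box

        lake = geo.LakeGeometry(
            "strip",
            box(0, 0, 3000, 400),
            [
                geo.Access("P1", 400.0, 0.0, geo.PUBLIC),
                geo.Access("P2", 900.0, 0.0, geo.PUBLIC),
                geo.Access("V1", 1200.0, 0.0, geo.PRIVATE),
            ],
        )
        assert geo.count_accesses_within((0.0, 0.0), lake, radius=1000.0) == (2, 0)
        assert geo.count_accesses_within((2500.0, 200.0), lake, radius=100.0) == (0, 0)

    def test_access_behind_island_excluded_by_boat_distance(self, island_lake):
        # the eastern access is 800 m away in a straight line from this
        # point, but the island forces a ~858 m detour
        p = (200.0, 300.0)
        net = geo.BoatNetwork(island_lake)
        d_east = net.access_distances(p)[1]  # accesses sorted: A00 west, A01 east
        euclid = math.hypot(1000.0 - p[0], 0.0)
        assert d_east > euclid
        oracle = grid_dijkstra_oracle(island_lake.polygon, p, (1000.0, 300.0), 5.0)
        assert abs(d_east - oracle) / d_east < 0.01
        n_pub, n_priv = geo.count_accesses_within(p, island_lake, radius=euclid + 50)
        assert n_priv == 0  # Euclidean-near but boat-far

    def test_access_off_shoreline_rejected(self, rect_lake):
        with pytest.raises(GeometryError, match="shoreline"):
            geo.LakeGeometry(
                "bad", rect_lake.polygon, [geo.Access("X", 1000.0, 50.0, geo.PUBLIC)]
            )


class TestDedup:
    def frame(self, coords, lake="L"):
        return pd.DataFrame(
            {
                "point_id": [f"obs{i}" for i in range(len(coords))],
                "lake_id": lake,
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
            }
        )

    def test_pair_within_threshold_merges(self):
        assign, canon = geo.dedup_points(self.frame([(0, 0), (8, 0)]))
        assert assign.nunique() == 1
        assert len(canon) == 1
        assert canon.loc[0, "x"] == pytest.approx(4.0)

    def test_pair_beyond_threshold_stays_distinct(self):
        assign, canon = geo.dedup_points(self.frame([(0, 0), (11, 0)]))
        assert assign.nunique() == 2

    def test_single_linkage_chains_transitively(self):
        # A-B 8 m, B-C 8 m, A-C 16 m: one cluster of three
        assign, canon = geo.dedup_points(self.frame([(0, 0), (8, 0), (16, 0)]))
        assert assign.nunique() == 1
        assert canon.loc[0, "n_obs"] == 3
        assert canon.loc[0, "x"] == pytest.approx(8.0)

    def test_order_invariance(self, rng):
        coords = [(rng.uniform(0, 200), rng.uniform(0, 200)) for _ in range(40)]
        df = self.frame(coords)
        a1, c1 = geo.dedup_points(df)
        shuffled = df.sample(frac=1.0, random_state=3)
        a2, c2 = geo.dedup_points(shuffled)
        pd.testing.assert_frame_equal(c1, c2)
        # same partition of observations regardless of order
        assert (a2.sort_index() == a1).all()

    def test_lakes_never_share_clusters(self):
        df = pd.concat(
            [self.frame([(0, 0)], "L1"), self.frame([(1, 0)], "L2")]
        ).reset_index(drop=True)
        assign, canon = geo.dedup_points(df)
        assert assign.nunique() == 2
        assert set(canon["lake_id"]) == {"L1", "L2"}
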