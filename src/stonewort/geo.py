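"""Computational geometry for within-lake occupancy predictors.

All geometry is planar, in meters, in a projected CRS; reprojection is an
I/O concern handled upstream.  A lake is a single (merged) water polygon
with optional holes for islands, plus geotagged boat accesses snapped to
the shoreline.

Predictors derived here:

- wind fetch at a point: the longest connected in-water chord through the
  point over a set of equally spaced bearings (islands truncate a chord,
  since fetch proxies uninterrupted wind run);
- boat-travel distance: shortest path between two in-water points that
  does not cross land, via a visibility graph over polygon vertices;
- nearest access (distance and public/private type) and counts of
  accesses within a radius, both "as the boat travels";
- deduplication of repeat survey locations by single-linkage clustering
  at a GPS-error threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon

from stonewort.errors import ConfigurationError, GeometryError, NoPathError

#: Analysis-set depth cutoff in meters (30 ft); strictly shallower points only.
DEPTH_CUTOFF_M = 9.14
#: GPS-error threshold (m) under which repeat observations are one point.
DEDUP_THRESHOLD_M = 10.0
#: Number of fetch bearings (10 degree spacing; undirected pairs collapse).
N_BEARINGS = 36
#: Radius (m) for local access-density counts.
ACCESS_RADIUS_M = 1000.0

PUBLIC = "public"
PRIVATE = "private"


@dataclass(frozen=True, order=True)
class Access:
    """A boat access point on the shoreline.

    ``kind`` is 'public' or 'private'; private maps to indicator 1 in the
    design matrix, public to 0.
    """

    access_id: str
    x: float
    y: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (PUBLIC, PRIVATE):
            raise ConfigurationError(
                f"access {self.access_id!r}: kind must be 'public' or 'private', "
                f"got {self.kind!r}"
            )

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)

    @property
    def private_indicator(self) -> int:
        return int(self.kind == PRIVATE)


@dataclass
class LakeGeometry:
    """Water polygon (holes = islands) plus shoreline accesses.

    Accesses farther than ``snap_tol`` from the boundary are rejected;
    nearer ones are snapped onto the boundary.
    """

    lake_id: str
    polygon: Polygon
    accesses: list[Access] = field(default_factory=list)
    snap_tol: float = 5.0

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            raise GeometryError(f"lake {self.lake_id!r}: expected a non-empty polygon")
        if not self.polygon.is_valid:
            raise GeometryError(f"lake {self.lake_id!r}: invalid polygon")
        if self.polygon.area <= 0:
            raise GeometryError(f"lake {self.lake_id!r}: degenerate polygon")
        boundary = self.polygon.boundary
        snapped = []
        for a in self.accesses:
            p = Point(a.x, a.y)
            if p.distance(boundary) > self.snap_tol:
                raise GeometryError(
                    f"lake {self.lake_id!r}: access {a.access_id!r} is "
                    f"{p.distance(boundary):.1f} m from the shoreline "
                    f"(snap tolerance {self.snap_tol} m)"
                )
            q = boundary.interpolate(boundary.project(p))
            snapped.append(Access(a.access_id, q.x, q.y, a.kind))
        self.accesses = sorted(snapped)
        shapely.prepare(self.polygon)

    @property
    def diameter(self) -> float:
        minx, miny, maxx, maxy = self.polygon.bounds
        return math.hypot(maxx - minx, maxy - miny)

    def contains(self, xy: tuple[float, float]) -> bool:
        return bool(self.polygon.covers(Point(xy)))


def merge_waterbodies(lake_id: str, polygons: list[Polygon], **kw) -> LakeGeometry:
    """Union directly connected waterbodies into one lake polygon."""
    merged = shapely.unary_union(polygons)
    if merged.geom_type == "MultiPolygon":
        raise GeometryError(
            f"lake {lake_id!r}: waterbodies are not connected; got "
            f"{len(merged.geoms)} disjoint parts"
        )
    return LakeGeometry(lake_id, merged, **kw)


# ---------------------------------------------------------------------------
# Fetch
# ---------------------------------------------------------------------------

def _undirected_bearings(n_bearings: int) -> np.ndarray:
    """Collapse n equally spaced compass bearings to unique undirected lines."""
    if n_bearings < 1:
        raise ValueError("n_bearings must be >= 1")
    theta = (np.arange(n_bearings) * (360.0 / n_bearings)) % 180.0
    return np.unique(np.round(theta, 9))


def compute_fetch(
    point: tuple[float, float],
    lake: LakeGeometry,
    n_bearings: int = N_BEARINGS,
) -> float:
    """Maximum connected in-water chord length through ``point``.

    Lines are forced through the point at ``n_bearings`` equally spaced
    bearings (36 -> 10 degree intervals, i.e. 18 undirected lines); each is
    clipped by the outer shoreline and island holes, and only the connected
    water segment containing the point counts.
    """
    p = Point(point)
    if not lake.polygon.covers(p):
        raise GeometryError(
            f"lake {lake.lake_id!r}: fetch point {point} is not in the water polygon"
        )
    half = lake.diameter * 1.001
    best = 0.0
    for theta in _undirected_bearings(n_bearings):
        # compass bearing: 0 = north, clockwise
        dx = math.sin(math.radians(theta))
        dy = math.cos(math.radians(theta))
        line = LineString(
            [
                (point[0] - half * dx, point[1] - half * dy),
                (point[0] + half * dx, point[1] + half * dy),
            ]
        )
        inter = lake.polygon.intersection(line)
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type != "LineString" or g.is_empty:
                continue
            if g.distance(p) < 1e-9:  # the segment containing the point
                best = max(best, g.length)
    return best


# ---------------------------------------------------------------------------
# Boat-travel distance
# ---------------------------------------------------------------------------

def _polygon_vertices(poly: Polygon) -> np.ndarray:
    coords = list(poly.exterior.coords[:-1])
    for ring in poly.interiors:
        coords.extend(ring.coords[:-1])
    return np.asarray(coords, dtype=float)


class BoatNetwork:
    """Visibility-graph shortest paths within a lake polygon.

    Nodes are the polygon's shell and hole vertices plus the lake's
    accesses; an edge is admitted when the connecting segment lies
    entirely in water (boundary included).  Query points are attached on
    the fly.  Distances between accesses and all graph nodes are
    precomputed so nearest-access and within-radius counts are cheap per
    survey point.
    """

    #: tolerance buffer (m) for edge admission; boundary-snapped nodes can
    #: sit a few ulps outside the polygon after projection
    EDGE_TOL = 1e-6

    def __init__(self, lake: LakeGeometry):
        self.lake = lake
        self._admission = lake.polygon.buffer(self.EDGE_TOL, quad_segs=2)
        shapely.prepare(self._admission)
        verts = _polygon_vertices(lake.polygon)
        acc = np.asarray([[a.x, a.y] for a in lake.accesses], dtype=float).reshape(-1, 2)
        self.nodes = np.vstack([verts, acc]) if len(acc) else verts
        self.n_nodes = len(self.nodes)
        self.access_idx = np.arange(len(verts), len(verts) + len(acc))
        ii, jj = np.triu_indices(self.n_nodes, k=1)
        vis = self._segments_in_water(self.nodes[ii], self.nodes[jj])
        ii, jj = ii[vis], jj[vis]
        w = np.hypot(*(self.nodes[ii] - self.nodes[jj]).T)
        graph = coo_matrix((w, (ii, jj)), shape=(self.n_nodes, self.n_nodes))
        self._graph = (graph + graph.T).tocsr()
        # all-pairs node distances; lakes have at most a few hundred vertices
        self._node_dist = dijkstra(self._graph, directed=False)
        self._acc_node_dist = (
            self._node_dist[self.access_idx] if len(acc) else np.empty((0, self.n_nodes))
        )

    def _segments_in_water(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        segs = shapely.linestrings(np.stack([a, b], axis=1))
        return shapely.covers(self._admission, segs)

    def _attach(self, xy: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        """Visibility mask and Euclidean distances from a point to all nodes."""
        p = np.asarray(xy, dtype=float)
        if not self.lake.polygon.covers(Point(xy)) and not self._admission.covers(
            Point(xy)
        ):
            raise GeometryError(
                f"lake {self.lake.lake_id!r}: point {tuple(xy)} is on land"
            )
        src = np.broadcast_to(p, self.nodes.shape)
        mask = self._segments_in_water(src, self.nodes)
        d = np.hypot(*(self.nodes - p).T)
        return mask, d

    def distance(self, origin: tuple[float, float], target: tuple[float, float]) -> float:
        """Shortest water-constrained path length between two points."""
        o = np.asarray(origin, dtype=float)
        t = np.asarray(target, dtype=float)
        if np.allclose(o, t):
            if not self.lake.polygon.covers(Point(origin)):
                raise GeometryError(
                    f"lake {self.lake.lake_id!r}: point {tuple(o)} is on land"
                )
            return 0.0
        if self._segments_in_water(o[None], t[None])[0]:
            # covers() also validates both endpoints are in water
            return float(np.hypot(*(o - t)))
        mo, do = self._attach(origin)
        mt, dt = self._attach(target)
        if not mo.any() or not mt.any():
            raise NoPathError(
                f"lake {self.lake.lake_id!r}: no water path between "
                f"{tuple(o)} and {tuple(t)}"
            )
        through = do[mo, None] + self._node_dist[np.ix_(mo, mt)] + dt[None, mt]
        best = float(np.min(through))
        if not np.isfinite(best):
            raise NoPathError(
                f"lake {self.lake.lake_id!r}: water between {tuple(o)} and "
                f"{tuple(t)} is disconnected"
            )
        return best

    def access_distances(self, xy: tuple[float, float]) -> np.ndarray:
        """Boat distance from a point to every access (lake.accesses order)."""
        if not len(self.access_idx):
            return np.empty(0)
        mask, d = self._attach(xy)
        acc_xy = self.nodes[self.access_idx]
        src = np.broadcast_to(np.asarray(xy, dtype=float), acc_xy.shape)
        direct_vis = self._segments_in_water(src, acc_xy)
        direct = np.where(direct_vis, np.hypot(*(acc_xy - np.asarray(xy)).T), np.inf)
        if mask.any():
            via = np.min(self._acc_node_dist[:, mask] + d[None, mask], axis=1)
        else:
            via = np.full(len(acc_xy), np.inf)
        return np.minimum(direct, via)


def boat_distance(
    origin: tuple[float, float],
    target: tuple[float, float],
    lake: LakeGeometry,
    network: BoatNetwork | None = None,
) -> float:
    """Shortest path between two in-lake points that stays in the water.

    Equals the Euclidean distance whenever the straight segment is
    unobstructed; otherwise routes through the visibility graph over the
    polygon's vertices.
    """
    return (network or BoatNetwork(lake)).distance(origin, target)


def nearest_access(
    point: tuple[float, float],
    lake: LakeGeometry,
    network: BoatNetwork | None = None,
) -> tuple[float, str]:
    """Boat distance to, and kind of, the nearest access of either type.

    Exact distance ties break to the smaller access_id (accesses are kept
    sorted by id).
    """
    if not lake.accesses:
        raise ConfigurationError(f"lake {lake.lake_id!r} has no accesses")
    d = (network or BoatNetwork(lake)).access_distances(point)
    if not np.isfinite(d).any():
        raise NoPathError(
            f"lake {lake.lake_id!r}: no access reachable by water from {point}"
        )
    k = int(np.argmin(d))  # argmin returns the first (= smallest id) on ties
    return float(d[k]), lake.accesses[k].kind


def count_accesses_within(
    point: tuple[float, float],
    lake: LakeGeometry,
    radius: float = ACCESS_RADIUS_M,
    network: BoatNetwork | None = None,
) -> tuple[int, int]:
    """(n_public, n_private) accesses within ``radius`` by boat travel."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = (network or BoatNetwork(lake)).access_distances(point)
    kinds = np.array([a.kind for a in lake.accesses])
    near = d <= radius
    return int(np.sum(near & (kinds == PUBLIC))), int(np.sum(near & (kinds == PRIVATE)))


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def dedup_points(
    raw_points: pd.DataFrame,
    threshold: float = DEDUP_THRESHOLD_M,
) -> tuple[pd.Series, pd.DataFrame]:
    """Collapse repeat observations <= ``threshold`` m apart into one point.

    Within each lake, observations are grouped by single-linkage clustering
    (the transitive closure of the pairwise <= threshold relation); each
    cluster becomes one canonical point at the cluster centroid.  Output is
    independent of input row order: canonical ids are assigned by sorting
    cluster centroids lexicographically within lake.

    Parameters
    ----------
    raw_points : DataFrame with columns ``lake_id, x, y`` (one row per
        observation; repeated coordinates allowed).
    threshold : linkage distance in meters (> 0).

    Returns
    -------
    assignment : Series of canonical point_id aligned with ``raw_points``.
    canonical : DataFrame ``point_id, lake_id, x, y, n_obs`` (centroids).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for col in ("lake_id", "x", "y"):
        if col not in raw_points.columns:
            raise ConfigurationError(f"dedup_points: missing column {col!r}")
    assignment = pd.Series(index=raw_points.index, dtype=object)
    canon_rows = []
    for lake_id, grp in raw_points.groupby("lake_id", sort=True):
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        n = len(xy)
        pairs = cKDTree(xy).query_pairs(r=threshold, output_type="ndarray")
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        centroids = np.stack(
            [np.mean(xy[labels == c], axis=0) for c in range(labels.max() + 1)]
        )
        # order clusters by centroid so ids do not depend on row order
        order = np.lexsort((centroids[:, 1], centroids[:, 0]))
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(len(order))
        ids = np.array([f"{lake_id}-P{r:05d}" for r in rank])
        assignment.loc[grp.index] = ids[labels]
        for c in range(len(centroids)):
            canon_rows.append(
                {
                    "point_id": ids[c],
                    "lake_id": lake_id,
                    "x": centroids[c, 0],
                    "y": centroids[c, 1],
                    "n_obs": int(np.sum(labels == c)),
                }
            )
    canonical = (
        pd.DataFrame(canon_rows).sort_values(["lake_id", "point_id"]).reset_index(drop=True)
    )
    return assignment, canonical


# ---------------------------------------------------------------------------
# Predictor table
# ---------------------------------------------------------------------------

def derive_predictors(
    lakes: dict[str, LakeGeometry],
    points: pd.DataFrame,
    n_bearings: int = N_BEARINGS,
    access_radius: float = ACCESS_RADIUS_M,
) -> pd.DataFrame:
    """Geometry-derived occupancy predictors for canonical survey points.

    Returns one row per point: fetch_m, dist_access_m, access_private,
    n_public_1km, n_private_1km.
    """
    out = []
    for lake_id, grp in points.groupby("lake_id", sort=True):
        if lake_id not in lakes:
            raise ConfigurationError(f"no geometry for lake {lake_id!r}")
        lake = lakes[lake_id]
        net = BoatNetwork(lake)
        for row in grp.itertuples():
            xy = (row.x, row.y)
            dist, kind = nearest_access(xy, lake, network=net)
            n_pub, n_priv = count_accesses_within(xy, lake, access_radius, network=net)
            out.append(
                {
                    "point_id": row.point_id,
                    "lake_id": lake_id,
                    "fetch_m": compute_fetch(xy, lake, n_bearings),
                    "dist_access_m": dist,
                    "access_private": int(kind == PRIVATE),
                    "n_public_1km": n_pub,
                    "n_private_1km": n_priv,
                }
            )
    return pd.DataFrame(out)
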