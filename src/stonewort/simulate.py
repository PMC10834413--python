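"""Synthetic lakes, survey grids and visit data from the generative model.

The generator emulates gridded littoral point-intercept surveys over
several lakes and years: lake polygons (with optional islands), shoreline
boat accesses, a depth field increasing away from shore, rake-abundance
tables for non-target taxa, and latent occupancy/detection drawn from the
occupancy model itself.  Geometry predictors are computed through the real
``geo``/``covariates`` code so every pipeline stage is exercised.

The latent spatial field is drawn from the *dense* Gaussian process (not
the NNGP), so fitting with the NNGP tests the approximation rather than a
self-fulfilling identity.  True coefficients live on the standardized
covariate scale, i.e. exactly the scale the model estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from shapely.geometry import Point

from stonewort import covariates, geo
from stonewort.errors import ConfigurationError, GeometryError

TARGET_TAXON = "Nitellopsis obtusa"
CHARACEAE_TAXA = ("Chara sp.", "Nitella sp.")
OTHER_TAXA = ("Potamogeton sp.", "Ceratophyllum demersum")

#: True occupancy coefficients (standardized scale) for the desk scenario.
DEFAULT_BETA = {
    "intercept": -0.5,
    "depth": -1.6,
    "time_since_infestation": 1.7,
    "dist_access": -1.1,
    "access_private": 0.9,
    "n_public_1km": -0.2,
    "n_private_1km": -0.05,
    "fetch": 0.25,
    "depth_x_fetch": -0.55,
}
#: True detection coefficients; the intercept gives ~63% detection at
#: scaled-mean covariates.
DEFAULT_ALPHA = {
    "intercept": 0.534,
    "plant_density": -0.348,
    "characeae_density": -0.165,
    "day_of_year": 0.034,
}


@dataclass(frozen=True)
class LakeSpec:
    """Shape and survey schedule for one synthetic lake."""

    lake_id: str
    center: tuple[float, float]
    radius: float = 500.0
    aspect: float = 1.0            # <1 squashes the circle into an ellipse
    island_radius: float = 0.0     # 0 = no island
    island_offset: tuple[float, float] = (0.0, 0.0)
    n_public: int = 2
    n_private: int = 1
    first_infested_year: int = 2016
    survey_years: tuple[int, ...] = (2019, 2020, 2021)
    visits_per_year: int = 1
    state: str = "SIM"


def default_lake_specs() -> tuple[LakeSpec, ...]:
    """Five-lakes desk scenario: varied shapes, accesses and infestation years."""
    return (
        LakeSpec("L01", (0.0, 0.0), radius=500.0, n_public=2, n_private=1,
                 first_infested_year=2015, visits_per_year=2),
        LakeSpec("L02", (20_000.0, 0.0), radius=520.0, aspect=0.7, n_public=1,
                 n_private=1, first_infested_year=2016),
        LakeSpec("L03", (40_000.0, 0.0), radius=480.0, island_radius=90.0,
                 island_offset=(120.0, 60.0), n_public=2, n_private=0,
                 first_infested_year=2017, visits_per_year=2),
        LakeSpec("L04", (60_000.0, 0.0), radius=540.0, aspect=0.85, n_public=1,
                 n_private=2, first_infested_year=2018),
        LakeSpec("L05", (80_000.0, 0.0), radius=460.0, n_public=3, n_private=0,
                 first_infested_year=2019),
    )


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the desk-scale conditions: 5 lakes of roughly 150
    retained grid points each (65 m spacing), 3 survey years with 1-2
    visits per year, detection intercept giving ~63% per-visit detection
    at mean covariates, and moderate spatial/lake random-effect variances.
    """

    lakes: tuple[LakeSpec, ...] = field(default_factory=default_lake_specs)
    grid_spacing: float = 65.0
    depth_slope: float = 0.035       # m of depth per m of distance from shore
    depth_noise_sd: float = 0.3      # point-level bathymetric roughness (m)
    depth_obs_sd: float = 0.1        # per-visit depth measurement error (m)
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    phi: float = 0.006               # spatial decay (1/m); range ~500 m
    sigma2: float = 1.0              # spatial random-effect variance
    sigma2_lake: float = 0.5         # lake-intercept variance
    season: tuple[int, int] = (152, 273)  # survey window, day of year
    jitter: float = 1e-8

    @property
    def target_taxon(self) -> str:
        return TARGET_TAXON

    @property
    def characeae_taxa(self) -> tuple[str, ...]:
        return CHARACEAE_TAXA


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

def _lake_polygon(spec: LakeSpec) -> shapely.Polygon:
    shell = Point(spec.center).buffer(spec.radius, quad_segs=24)
    if spec.aspect != 1.0:
        shell = shapely.affinity.scale(shell, xfact=1.0, yfact=spec.aspect,
                                       origin=spec.center)
    if spec.island_radius > 0:
        hole = Point(
            spec.center[0] + spec.island_offset[0],
            spec.center[1] + spec.island_offset[1],
        ).buffer(spec.island_radius, quad_segs=16)
        shell = shell.difference(hole)
    return shell


def _shoreline_accesses(spec: LakeSpec, poly: shapely.Polygon,
                        rng: np.random.Generator) -> list[geo.Access]:
    ring = poly.exterior
    kinds = [geo.PUBLIC] * spec.n_public + [geo.PRIVATE] * spec.n_private
    fracs = np.sort(rng.uniform(0, 1, size=len(kinds)))
    accesses = []
    for i, (kind, fr) in enumerate(zip(kinds, fracs)):
        p = ring.interpolate(fr * ring.length)
        accesses.append(geo.Access(f"{spec.lake_id}-A{i:02d}", p.x, p.y, kind))
    return accesses


def grid_points(poly: shapely.Polygon, spacing: float) -> np.ndarray:
    """Grid intersections strictly inside the water polygon."""
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be positive")
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    if len(xs) == 0 or len(ys) == 0:
        raise GeometryError("grid spacing is larger than the lake")
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    inside = shapely.contains(poly, pts)
    if not inside.any():
        raise GeometryError("no grid point falls inside the lake")
    return np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])


def generate_lakes(
    scenario: SimScenario, seed: int | np.random.SeedSequence = 0
) -> tuple[dict[str, geo.LakeGeometry], pd.DataFrame]:
    """Lake geometries plus the gridded survey points with true depths.

    Returns (lakes, points) where points has columns point_id, lake_id,
    x, y, depth_true.  Depth increases with distance from shore (slope *
    distance + noise); points deeper than the analysis cutoff are
    generated on purpose so the pipeline's depth filter is exercised.
    """
    rng = np.random.default_rng(seed)
    lakes: dict[str, geo.LakeGeometry] = {}
    rows = []
    for spec in scenario.lakes:
        poly = _lake_polygon(spec)
        lake = geo.LakeGeometry(spec.lake_id, poly,
                                _shoreline_accesses(spec, poly, rng))
        lakes[spec.lake_id] = lake
        xy = grid_points(poly, scenario.grid_spacing)
        boundary = poly.boundary
        d_shore = np.array([boundary.distance(Point(p)) for p in xy])
        depth = (
            d_shore * scenario.depth_slope
            + rng.normal(0.0, scenario.depth_noise_sd, size=len(xy))
        )
        depth = np.clip(depth, 0.15, None)
        for i, ((x, y), dep) in enumerate(zip(xy, depth)):
            rows.append(
                {
                    "point_id": f"{spec.lake_id}-P{i:04d}",
                    "lake_id": spec.lake_id,
                    "x": float(x),
                    "y": float(y),
                    "depth_true": float(dep),
                }
            )
    return lakes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def _dense_gp_draw(coords: np.ndarray, phi: float, sigma2: float,
                   jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the dense exponential-kernel GP (not the NNGP)."""
    n = len(coords)
    if sigma2 == 0.0:
        return np.zeros(n)
    from scipy.spatial.distance import pdist, squareform

    K = sigma2 * np.exp(-phi * squareform(pdist(coords)))
    K[np.diag_indices(n)] += max(jitter, 1e-12) * sigma2
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as err:
        raise GeometryError("GP kernel matrix not positive definite") from err
    return L @ rng.standard_normal(n)


def _rake_long_table(
    scenario: SimScenario,
    points: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format rake table for all visits, target ordinals set to 0.

    Each (lake, year, visit) survey event gets one date in the survey
    window; per-visit ordinals for non-target taxa come from a per-point
    latent propensity plus visit noise, cut into the ordinal scale.
    Characeae are a component of the total, so plant and Characeae density
    are positively correlated by construction.
    """
    spec_by_lake = {s.lake_id: s for s in scenario.lakes}
    taxa = list(CHARACEAE_TAXA) + list(OTHER_TAXA)
    # ordinal cutpoints on a standard-normal propensity: ~(50, 25, 15, 10)%
    cuts = np.array([0.0, 0.675, 1.28])
    rows = []
    for lake_id, grp in points.groupby("lake_id", sort=True):
        spec = spec_by_lake[lake_id]
        prop = {t: rng.normal(0, 1, size=len(grp)) for t in taxa}
        for year in spec.survey_years:
            for k in range(spec.visits_per_year):
                doy = int(rng.integers(scenario.season[0], scenario.season[1] + 1))
                date = (
                    pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=doy - 1)
                ).date()
                depth_obs = grp["depth_true"].to_numpy() + rng.normal(
                    0, scenario.depth_obs_sd, size=len(grp)
                )
                for t in taxa:
                    lat = 0.6 * prop[t] + 0.8 * rng.normal(0, 1, size=len(grp))
                    ordinal = np.searchsorted(cuts, lat, side="left")
                    for pid, dep, o in zip(grp["point_id"], depth_obs, ordinal):
                        if o > 0:
                            rows.append((pid, lake_id, str(date), float(dep), t, int(o)))
                # explicit zero row for the target so every visit appears
                for pid, dep in zip(grp["point_id"], depth_obs):
                    rows.append((pid, lake_id, str(date), float(dep), TARGET_TAXON, 0))
    return pd.DataFrame(
        rows, columns=["point_id", "lake_id", "date", "depth_m", "taxon", "ordinal"]
    )


@dataclass
class SimResult:
    """Observable tables plus the hidden truth for recovery testing."""

    lakes: dict[str, geo.LakeGeometry]
    points: pd.DataFrame          # canonical points (point_id, lake_id, x, y)
    long_visits: pd.DataFrame     # rake table incl. target detections
    visits: pd.DataFrame          # reduced per-visit table
    lake_meta: pd.DataFrame
    geo_predictors: pd.DataFrame
    design: covariates.OccupancyDesign
    truth: dict

    @property
    def scenario(self) -> SimScenario:
        return self.truth["scenario"]


def simulate_truth(
    scenario: SimScenario,
    lakes: dict[str, geo.LakeGeometry],
    points: pd.DataFrame,
    seed: int | np.random.SeedSequence = 0,
) -> SimResult:
    """Draw latent occupancy and visit detections from the model.

    Covariates flow through the real predictor code: geometry predictors
    from :mod:`stonewort.geo`, design standardization from
    :mod:`stonewort.covariates`.  w is drawn from the exact dense GP,
    gamma_j iid N(0, sigma2_lake); z_ijt independently per point-year
    given the effects (no explicit colonization dynamics); y via the
    detection model at occupied point-years only.
    """
    rng = np.random.default_rng(seed)
    missing = [k for k in DEFAULT_BETA if k not in scenario.beta]
    if missing:
        raise ConfigurationError(f"scenario.beta missing coefficients {missing}")

    long0 = _rake_long_table(scenario, points, rng)
    visits0 = covariates.reduce_rake_table(long0, CHARACEAE_TAXA, TARGET_TAXON)
    geo_pred = geo.derive_predictors(lakes, points)
    lake_meta = pd.DataFrame(
        [
            {
                "lake_id": s.lake_id,
                "first_infested_year": s.first_infested_year,
                "state": s.state,
            }
            for s in scenario.lakes
        ]
    )
    design = covariates.assemble_design(
        points[["point_id", "lake_id", "x", "y"]], visits0, lake_meta, geo_pred
    )

    beta = np.array([scenario.beta[c] for c in design.x_names])
    alpha = np.array([scenario.alpha[c] for c in design.v_names])
    w = _dense_gp_draw(design.point_coords, scenario.phi, scenario.sigma2,
                       scenario.jitter, rng)
    gamma = rng.normal(0.0, np.sqrt(scenario.sigma2_lake), size=design.n_lakes)
    psi = expit(design.X @ beta + w[design.py_point_idx] + gamma[design.py_lake_idx])
    z = (rng.uniform(size=len(psi)) < psi).astype(np.int8)
    p_vis = expit(design.V @ alpha)
    y = ((rng.uniform(size=len(p_vis)) < p_vis) & (z[design.visit_py_idx] == 1)).astype(
        np.int8
    )

    # write detections back into the rake table (target ordinal 1 = present)
    vis_key = design.visits[["point_id", "date"]].astype({"date": str})
    y_by_visit = dict(zip(zip(vis_key["point_id"], vis_key["date"]), y))
    long1 = long0.copy()
    tgt = long1["taxon"] == TARGET_TAXON
    long1.loc[tgt, "ordinal"] = [
        int(y_by_visit.get((p, d), 0))
        for p, d in zip(long1.loc[tgt, "point_id"], long1.loc[tgt, "date"])
    ]
    visits1 = covariates.reduce_rake_table(long1, CHARACEAE_TAXA, TARGET_TAXON)
    design1 = covariates.assemble_design(
        points[["point_id", "lake_id", "x", "y"]], visits1, lake_meta, geo_pred
    )
    assert np.allclose(design1.X, design.X) and np.allclose(design1.V, design.V)

    truth = {
        "scenario": scenario,
        "beta": dict(zip(design.x_names, beta)),
        "alpha": dict(zip(design.v_names, alpha)),
        "phi": scenario.phi,
        "sigma2": scenario.sigma2,
        "sigma2_lake": scenario.sigma2_lake,
        "w": dict(zip(design.point_table["point_id"], w)),
        "gamma": dict(zip(design.lake_ids, gamma)),
        "psi": psi,
        "z": z,
    }
    return SimResult(
        lakes=lakes,
        points=points[["point_id", "lake_id", "x", "y"]].copy(),
        long_visits=long1,
        visits=visits1,
        lake_meta=lake_meta,
        geo_predictors=geo_pred,
        design=design1,
        truth=truth,
    )


def simulate_dataset(
    scenario: SimScenario | None = None, seed: int = 0
) -> SimResult:
    """Generate geometry and draw one dataset in a single call."""
    scenario = scenario or SimScenario()
    ss = np.random.SeedSequence(seed)
    geom_seed, truth_seed = ss.spawn(2)
    lakes, points = generate_lakes(scenario, geom_seed)
    return simulate_truth(scenario, lakes, points, truth_seed)


def write_fixture(sim: SimResult, directory: str | Path) -> dict[str, Path]:
    """Persist a simulated dataset in the formats the pipeline ingests.

    Emits lakes+accesses GeoJSON, long-format visits CSV, points CSV,
    lake metadata CSV, and truth.json with the hidden parameters.
    Deterministic content for a fixed simulation.
    """
    from stonewort import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "lakes": directory / "lakes.geojson",
        "points": directory / "points.csv",
        "visits": directory / "visits.csv",
        "lake_meta": directory / "lake_meta.csv",
        "truth": directory / "truth.json",
    }
    sio.write_lakes_geojson(sim.lakes, paths["lakes"])
    sim.points.to_csv(paths["points"], index=False)
    sim.long_visits.to_csv(paths["visits"], index=False)
    sim.lake_meta.to_csv(paths["lake_meta"], index=False)
    truth = sim.truth
    payload = {
        "beta": truth["beta"],
        "alpha": truth["alpha"],
        "phi": truth["phi"],
        "sigma2": truth["sigma2"],
        "sigma2_lake": truth["sigma2_lake"],
        "gamma": {k: float(v) for k, v in truth["gamma"].items()},
        "w": {k: float(v) for k, v in truth["w"].items()},
        "scenario": _scenario_to_jsonable(truth["scenario"]),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def _scenario_to_jsonable(scenario: SimScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["lakes"] = [dataclasses.asdict(s) for s in scenario.lakes]
    return d
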