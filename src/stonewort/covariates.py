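"""Rake-table reduction and standardized design matrices.

The occupancy level of the model works on point-year rows (closure period
= calendar year; repeated surveys within a year are visits k within that
year).  The detection level works on visit rows.  All quantitative
covariates are mean-centered and scaled over the analysis set; the binary
nearest-access-type column is left unscaled.  Interaction columns are
products of the standardized main effects and are not re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from stonewort.errors import ConfigurationError, SchemaError
from stonewort.geo import DEPTH_CUTOFF_M

#: Ordinal rake-abundance scale -> proportion midpoints.
#: 0 = absent, 1 = <25%, 2 = 25-75%, 3 = >75% tine coverage.
MIDPOINTS = (0.0, 0.125, 0.5, 0.875)

#: Occupancy design columns, in order.
OCC_COLUMNS = [
    "intercept",
    "depth",
    "time_since_infestation",
    "dist_access",
    "access_private",
    "n_public_1km",
    "n_private_1km",
    "fetch",
    "depth_x_fetch",
]
#: Detection design columns, in order.
DET_COLUMNS = ["intercept", "plant_density", "characeae_density", "day_of_year"]

#: Quantitative occupancy columns that get standardized (binary type excluded).
_OCC_SCALED = [
    "depth",
    "time_since_infestation",
    "dist_access",
    "n_public_1km",
    "n_private_1km",
    "fetch",
]
_DET_SCALED = ["plant_density", "characeae_density", "day_of_year"]


def ordinal_to_midpoint(ordinal: int) -> float:
    """Map a rake ordinal {0,1,2,3} to its coverage-proportion midpoint."""
    o = int(ordinal)
    if o != ordinal or not 0 <= o <= 3:
        raise SchemaError(f"rake ordinal must be in {{0,1,2,3}}, got {ordinal!r}")
    return MIDPOINTS[o]


def density_covariates(
    taxon_abundances: Mapping[str, int],
    characeae_taxa: Iterable[str],
    target_taxon: str,
) -> tuple[float, float]:
    """(plant_density, characeae_density) for one rake sample.

    Sums of coverage midpoints over non-target taxa and non-target
    Characeae respectively; the target species is excluded from both.
    """
    characeae = set(characeae_taxa)
    plant = 0.0
    chara = 0.0
    for taxon, ordinal in taxon_abundances.items():
        if taxon == target_taxon:
            continue
        m = ordinal_to_midpoint(ordinal)
        plant += m
        if taxon in characeae:
            chara += m
    return plant, chara


def reduce_rake_table(
    long_visits: pd.DataFrame,
    characeae_taxa: Iterable[str],
    target_taxon: str,
) -> pd.DataFrame:
    """Collapse a long-format rake table to one row per visit.

    ``long_visits`` columns: point_id, lake_id, date, depth_m, taxon,
    ordinal (one row per taxon recovered; taxa absent from a sampled visit
    are ordinal 0 by protocol).  A visit is one (point_id, date) sampling
    event.  Returns per-visit detection of the target plus density
    covariates.
    """
    req = {"point_id", "lake_id", "date", "depth_m", "taxon", "ordinal"}
    missing = req - set(long_visits.columns)
    if missing:
        raise SchemaError(f"rake table is missing columns {sorted(missing)}")
    if long_visits["ordinal"].isna().any():
        raise SchemaError("rake table contains missing ordinals")
    bad = ~long_visits["ordinal"].isin([0, 1, 2, 3])
    if bad.any():
        raise SchemaError(
            f"rake ordinals outside {{0,1,2,3}}: "
            f"{sorted(long_visits.loc[bad, 'ordinal'].unique().tolist())}"
        )
    characeae = set(characeae_taxa)
    rows = []
    for (pid, date), grp in long_visits.groupby(["point_id", "date"], sort=True):
        abund = dict(zip(grp["taxon"], grp["ordinal"]))
        plant, chara = density_covariates(abund, characeae, target_taxon)
        rows.append(
            {
                "point_id": pid,
                "lake_id": grp["lake_id"].iloc[0],
                "date": date,
                "depth_m": float(grp["depth_m"].iloc[0]),
                "y": int(abund.get(target_taxon, 0) > 0),
                "plant_density": plant,
                "characeae_density": chara,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OccupancyDesign:
    """Aligned, standardized design matrices for one analysis set.

    Point-year rows (X) are ordered by (lake_id, point_id, year); visit
    rows (V) by (lake_id, point_id, year, visit).  ``scaling`` records the
    (mean, sd) used per quantitative column so predictions for new
    years/points reuse the training standardization.
    """

    X: np.ndarray
    x_names: list[str]
    V: np.ndarray
    v_names: list[str]
    y: np.ndarray                 # per-visit binary detection
    py: pd.DataFrame              # point-year rows: lake_id, point_id, year
    visits: pd.DataFrame          # visit rows incl. date, day_of_year, k
    visit_py_idx: np.ndarray      # visit -> point-year row
    det_any: np.ndarray           # per point-year: any detection
    point_table: pd.DataFrame     # per point: coords + unscaled medians
    point_coords: np.ndarray      # (n_points, 2), point_table order
    py_point_idx: np.ndarray      # point-year -> point row
    py_lake_idx: np.ndarray       # point-year -> lake index
    lake_ids: list[str]
    first_infested: dict[str, int]
    scaling: dict[str, tuple[float, float]]
    X_raw: pd.DataFrame = field(repr=False, default=None)
    V_raw: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return len(self.point_table)

    @property
    def n_lakes(self) -> int:
        return len(self.lake_ids)

    def standardize(self, col: str, values: np.ndarray) -> np.ndarray:
        mean, sd = self.scaling[col]
        return (np.asarray(values, dtype=float) - mean) / sd

    def occupancy_row(self, point_row: int, year: int) -> np.ndarray:
        """Standardized occupancy covariate row for a point at a given year."""
        pt = self.point_table.iloc[point_row]
        t_raw = year - self.first_infested[pt["lake_id"]]
        vals = {
            "intercept": 1.0,
            "depth": self.standardize("depth", pt["depth_m"]),
            "time_since_infestation": self.standardize("time_since_infestation", t_raw),
            "dist_access": self.standardize("dist_access", pt["dist_access_m"]),
            "access_private": float(pt["access_private"]),
            "n_public_1km": self.standardize("n_public_1km", pt["n_public_1km"]),
            "n_private_1km": self.standardize("n_private_1km", pt["n_private_1km"]),
            "fetch": self.standardize("fetch", pt["fetch_m"]),
        }
        vals["depth_x_fetch"] = vals["depth"] * vals["fetch"]
        if "dist_x_time" in self.x_names:
            vals["dist_x_time"] = vals["dist_access"] * vals["time_since_infestation"]
        return np.array([vals[c] for c in self.x_names])


def _standardize_frame(
    raw: pd.DataFrame, cols: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    out = raw.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for c in cols:
        mean = float(raw[c].mean())
        sd = float(raw[c].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise SchemaError(f"covariate {c!r} is constant; cannot standardize")
        out[c] = (raw[c] - mean) / sd
        scaling[c] = (mean, sd)
    return out, scaling


def assemble_design(
    points: pd.DataFrame,
    visits: pd.DataFrame,
    lake_meta: pd.DataFrame,
    geo_predictors: pd.DataFrame,
    add_distance_time_interaction: bool = False,
    depth_cutoff: float = DEPTH_CUTOFF_M,
) -> OccupancyDesign:
    """Build the standardized occupancy/detection design matrices.

    Parameters
    ----------
    points : canonical survey points (point_id, lake_id, x, y).
    visits : reduced visit table (point_id, lake_id, date, depth_m, y,
        plant_density, characeae_density); one row per rake sample.
    lake_meta : lake_id, first_infested_year.
    geo_predictors : output of :func:`stonewort.geo.derive_predictors`.

    Notes
    -----
    Occupancy covariates other than time-since-first-infestation are
    per-point medians across all surveys (depth fluctuation across visits
    is treated as measurement error).  Points at or beyond the depth
    cutoff are excluded (strict ``<``), together with their visits.
    Point-years with zero visits are allowed in principle but the
    analysis set is defined by observed visits.
    """
    visits = visits.copy()
    visits["date"] = pd.to_datetime(visits["date"])
    visits["year"] = visits["date"].dt.year
    visits["day_of_year"] = visits["date"].dt.dayofyear

    meta = lake_meta.set_index("lake_id")["first_infested_year"].to_dict()
    for lake_id in visits["lake_id"].unique():
        if lake_id not in meta:
            raise ConfigurationError(
                f"lake {lake_id!r} has visits but no first-infested year"
            )

    # per-point median depth across all surveys, then the depth filter
    med_depth = visits.groupby("point_id")["depth_m"].median().rename("depth_m")
    pt = (
        points.merge(med_depth, on="point_id", how="inner")
        .merge(geo_predictors.drop(columns=["lake_id"]), on="point_id", how="inner")
    )
    pt = pt[(pt["depth_m"] > 0) & (pt["depth_m"] < depth_cutoff)]
    pt = pt.sort_values(["lake_id", "point_id"]).reset_index(drop=True)
    if pt.empty:
        raise SchemaError("no survey points remain after the depth filter")
    visits = visits[visits["point_id"].isin(pt["point_id"])]

    # visit bookkeeping: k = 1..K within (point, year), ordered by date
    visits = visits.sort_values(["lake_id", "point_id", "year", "date"]).reset_index(
        drop=True
    )
    visits["k"] = visits.groupby(["point_id", "year"]).cumcount() + 1

    # point-year rows
    py = (
        visits[["lake_id", "point_id", "year"]]
        .drop_duplicates()
        .sort_values(["lake_id", "point_id", "year"])
        .reset_index(drop=True)
    )

    point_row = {pid: i for i, pid in enumerate(pt["point_id"])}
    lake_ids = sorted(pt["lake_id"].unique().tolist())
    lake_row = {lid: i for i, lid in enumerate(lake_ids)}

    pt_idx = pt.set_index("point_id")
    X_raw = pd.DataFrame(
        {
            "intercept": 1.0,
            "depth": pt_idx.loc[py["point_id"], "depth_m"].to_numpy(),
            "time_since_infestation": (
                py["year"] - py["lake_id"].map(meta)
            ).to_numpy(dtype=float),
            "dist_access": pt_idx.loc[py["point_id"], "dist_access_m"].to_numpy(),
            "access_private": pt_idx.loc[py["point_id"], "access_private"].to_numpy(
                dtype=float
            ),
            "n_public_1km": pt_idx.loc[py["point_id"], "n_public_1km"].to_numpy(
                dtype=float
            ),
            "n_private_1km": pt_idx.loc[py["point_id"], "n_private_1km"].to_numpy(
                dtype=float
            ),
            "fetch": pt_idx.loc[py["point_id"], "fetch_m"].to_numpy(),
        }
    )
    X_std, occ_scaling = _standardize_frame(X_raw, _OCC_SCALED)
    X_std["depth_x_fetch"] = X_std["depth"] * X_std["fetch"]
    x_names = list(OCC_COLUMNS)
    if add_distance_time_interaction:
        X_std["dist_x_time"] = X_std["dist_access"] * X_std["time_since_infestation"]
        x_names = x_names + ["dist_x_time"]

    V_raw = visits[_DET_SCALED].astype(float).copy()
    V_raw.insert(0, "intercept", 1.0)
    V_std, det_scaling = _standardize_frame(V_raw, _DET_SCALED)

    py_key = {tuple(r): i for i, r in enumerate(py[["point_id", "year"]].itertuples(index=False))}
    visit_py_idx = np.array(
        [py_key[(p, t)] for p, t in zip(visits["point_id"], visits["year"])]
    )
    y = visits["y"].to_numpy(dtype=np.int8)
    det_any = np.zeros(len(py), dtype=bool)
    np.logical_or.at(det_any, visit_py_idx, y.astype(bool))

    return OccupancyDesign(
        X=X_std[x_names].to_numpy(dtype=float),
        x_names=x_names,
        V=V_std[DET_COLUMNS].to_numpy(dtype=float),
        v_names=list(DET_COLUMNS),
        y=y,
        py=py,
        visits=visits,
        visit_py_idx=visit_py_idx,
        det_any=det_any,
        point_table=pt,
        point_coords=pt[["x", "y"]].to_numpy(dtype=float),
        py_point_idx=py["point_id"].map(point_row).to_numpy(),
        py_lake_idx=py["lake_id"].map(lake_row).to_numpy(),
        lake_ids=lake_ids,
        first_infested={k: int(v) for k, v in meta.items()},
        scaling={**occ_scaling, **det_scaling},
        X_raw=X_raw,
        V_raw=V_raw,
    )


def observed_occupancy_rates(design: OccupancyDesign) -> pd.Series:
    """Per-lake proportion of points with >= 1 detection across all surveys."""
    pt_det = pd.Series(False, index=design.point_table["point_id"])
    det_points = design.py.loc[design.det_any, "point_id"].unique()
    pt_det.loc[det_points] = True
    frame = design.point_table.assign(detected=pt_det.to_numpy())
    return frame.groupby("lake_id")["detected"].mean()
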