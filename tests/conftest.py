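"""Shared fixtures: small synthetic lakes and a compact simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from stonewort import geo, simulate


@pytest.fixture(scope="session")
def circle_lake() -> geo.LakeGeometry:
    """Polygonized circle of radius 500 m with one public access."""
    from shapely.geometry import Point

    poly = Point(0.0, 0.0).buffer(500.0, quad_segs=64)
    return geo.LakeGeometry(
        "circle", poly, [geo.Access("A00", 0.0, 500.0, geo.PUBLIC)], snap_tol=5.0
    )


@pytest.fixture(scope="session")
def rect_lake() -> geo.LakeGeometry:
    """Axis-aligned 2000 x 100 m rectangle, no accesses."""
    return geo.LakeGeometry("rect", box(0.0, 0.0, 2000.0, 100.0))


@pytest.fixture(scope="session")
def island_lake() -> geo.LakeGeometry:
    """1000 x 600 m rectangle with a central 400 x 200 m island.

    Points on opposite sides of the island must route around it, so
    boat distances exceed Euclidean ones.
    """
    shell = [(0, 0), (1000, 0), (1000, 600), (0, 600)]
    hole = [(300, 200), (700, 200), (700, 400), (300, 400)]
    poly = Polygon(shell, [hole])
    accesses = [
        geo.Access("A00", 0.0, 300.0, geo.PUBLIC),
        geo.Access("A01", 1000.0, 300.0, geo.PRIVATE),
    ]
    return geo.LakeGeometry("island", poly, accesses)


def small_scenario() -> simulate.SimScenario:
    """Two small lakes, fast to simulate and fit; used for pipeline tests."""
    lakes = (
        simulate.LakeSpec(
            "S1", (0.0, 0.0), radius=260.0, n_public=2, n_private=1,
            first_infested_year=2016, survey_years=(2020, 2021), visits_per_year=2,
        ),
        simulate.LakeSpec(
            "S2", (8000.0, 0.0), radius=240.0, aspect=0.8, n_public=1, n_private=0,
            first_infested_year=2018, survey_years=(2020, 2021), visits_per_year=1,
        ),
        simulate.LakeSpec(
            "S3", (16000.0, 0.0), radius=230.0, n_public=1, n_private=1,
            first_infested_year=2017, survey_years=(2020, 2021), visits_per_year=1,
        ),
    )
    return simulate.SimScenario(lakes=lakes, grid_spacing=80.0)


@pytest.fixture(scope="session")
def small_sim() -> simulate.SimResult:
    return simulate.simulate_dataset(small_scenario(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
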