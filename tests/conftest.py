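"""Shared fixtures: tiny geometries and a reusable synthetic season."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box as shapely_box

from boxvisits.simulate import SimulationConfig, simulate
from boxvisits.territories import StudyArea


@pytest.fixture
def square_area():
    return StudyArea(boundary=shapely_box(-50, -50, 150, 50))


def make_boxes(coords):
    return pd.DataFrame(
        [{"box_id": f"B{i:02d}", "x": x, "y": y} for i, (x, y) in enumerate(coords)]
    )


def make_attempts(box_ids, year=2020):
    return pd.DataFrame(
        [
            {
                "attempt_id": f"A{i}",
                "year": year,
                "box_id": b,
                "male_id": f"M{i}",
                "female_id": f"F{i}",
                "date_nest_start": pd.Timestamp(year, 4, 1),
                "date_first_egg": pd.Timestamp(year, 4, 15),
                "clutch_size": 10,
                "date_hatch": pd.Timestamp(year, 5, 8),
                "date_fledge": pd.Timestamp(year, 5, 28),
                "fate": "fledged",
                "is_replacement": False,
            }
            for i, b in enumerate(box_ids)
        ]
    )


def make_individuals(attempts, year=2020):
    rows = []
    for _, a in attempts.iterrows():
        for col, sex in (("male_id", "male"), ("female_id", "female")):
            rows.append(
                {
                    "individual_id": a[col],
                    "sex": sex,
                    "age_class": "adult",
                    "tag_date": pd.Timestamp(year, 1, 15),
                    "year": year,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_bundle():
    """One 10x10-grid season with default behavioral parameters."""
    cfg = SimulationConfig(seed=42, n_years=1, grid_nx=10, grid_ny=10)
    return simulate(cfg)


@pytest.fixture(scope="session")
def two_year_bundle():
    """Two consecutive 10x10-grid seasons (exercises dispersal)."""
    cfg = SimulationConfig(seed=7, n_years=2, grid_nx=10, grid_ny=10)
    return simulate(cfg)
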