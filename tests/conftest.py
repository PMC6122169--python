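"""Shared fixtures: small synthetic scenes sized for fast test runs."""

from __future__ import annotations

import numpy as np
import pytest

from islefill.grids import DEMGrid, GridMeta, LSTCube, month_sequence
from islefill.synthetic import MissingnessParams, SceneParams, make_scene

FAST_SCENE = dict(shape=(16, 16), n_years=2, seed=11)


@pytest.fixture(scope="session")
def scene_pair():
    """(truth, gappy) default-structure scene with moderate cloud gaps."""
    params = SceneParams(**FAST_SCENE)
    mparams = MissingnessParams(intercept=-2.6, seed=7)
    return make_scene(params, mparams)


@pytest.fixture(scope="session")
def truth_scene(scene_pair):
    return scene_pair[0]


@pytest.fixture(scope="session")
def gappy_scene(scene_pair):
    return scene_pair[1]


@pytest.fixture(scope="session")
def noise_free_scene():
    """Deterministic linear-in-elevation scene: exact recovery is possible."""
    params = SceneParams(
        shape=(12, 12),
        n_years=2,
        slice_anomaly_sd=0.0,
        pixel_noise_sd=0.0,
        windward_offset=0.0,
        seasonal_amplitude=0.0,
        seed=2,
    )
    truth, _ = make_scene(params, None)
    return truth


def full_land_cube(
    n_rows: int = 12,
    n_cols: int = 12,
    n_years: int = 5,
    start_year: int = 2001,
    fill=0.0,
    photoperiod: str = "Day",
) -> tuple[LSTCube, DEMGrid]:
    """An all-land, fully observed cube plus a congruent sloping DEM."""
    grid = GridMeta(n_rows=n_rows, n_cols=n_cols, origin_lon=37.0, origin_lat=-46.0)
    layers = month_sequence(start_year, n_years)
    values = np.full((n_rows, n_cols, len(layers)), float(fill))
    land = np.ones((n_rows, n_cols), dtype=bool)
    cube = LSTCube(grid=grid, photoperiod=photoperiod, layers=layers,
                   values=values, land_mask=land)
    elev = 40.0 * np.add.outer(np.arange(n_rows), np.arange(n_cols)).astype(float)
    return cube, DEMGrid(grid=grid, elevation=elev)
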