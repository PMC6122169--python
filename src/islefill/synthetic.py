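"""Synthetic island scenes with controllable statistical structure.

Generates a DEM with a steep single-peak elevational gradient, day/night
temperature cubes with a seasonal cycle, elevational lapse, a windward /
leeward (west-east) asymmetry, per-month anomalies and pixel noise, and a
cloud-gap missingness process that is spatially autocorrelated and biased
towards high elevations, daytime and spring months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from islefill.grids import (
    DEFAULT_RESOLUTION,
    DEMGrid,
    GridMeta,
    IslandScene,
    LSTCube,
    month_sequence,
)

#: Austral spring months (Southern Hemisphere).
SPRING_MONTHS = frozenset({9, 10, 11})


@dataclass
class SceneParams:
    """Parameters of a synthetic island scene.

    Temperatures follow, per land cell ``c`` and month-layer ``t`` of
    calendar month ``m``::

        T(c, t) = sea_level_temp
                  + seasonal_amplitude * cos(2*pi*(m - seasonal_phase)/12)
                  + lapse_rate * elev(c)
                  + windward_offset * windward(c)
                  + eta_t + eps(c, t)

    with ``eta_t ~ N(0, slice_anomaly_sd**2)`` shared by all cells of a
    layer and ``eps`` iid ``N(0, pixel_noise_sd**2)``.  The night cube has
    the same structure minus ``day_night_offset``, with independent noise.
    """

    shape: tuple[int, int] = (24, 24)
    peak_height: float = 1200.0
    sea_level_temp: float = 8.0
    seasonal_amplitude: float = 5.0
    seasonal_phase: int = 1  # warmest month (January = austral summer)
    lapse_rate: float = -0.0065  # degC per m
    windward_offset: float = 1.5
    day_night_offset: float = 6.0
    slice_anomaly_sd: float = 0.8
    pixel_noise_sd: float = 0.5
    n_years: int = 3
    start_year: int = 2001
    seed: int = 0
    origin_lon: float = 37.5
    origin_lat: float = -46.8
    resolution: float = DEFAULT_RESOLUTION
    roughness: float = 0.02  # relative amplitude of DEM roughness

    def __post_init__(self) -> None:
        if self.slice_anomaly_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")
        if self.lapse_rate > 0:
            raise ValueError("lapse_rate must be non-positive")


@dataclass
class MissingnessParams:
    """Logit-scale drivers of the synthetic cloud-gap process."""

    intercept: float = -2.0
    b_elev: float = 0.0015  # per metre
    b_day: float = 0.6
    b_spring: float = 0.8
    spatial_field_sd: float = 1.0
    correlation_range: float = 3.0  # cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_range <= 0:
            raise ValueError("correlation_range must be positive")
        if self.spatial_field_sd < 0:
            raise ValueError("spatial_field_sd must be non-negative")


def make_dem(params: SceneParams) -> tuple[DEMGrid, np.ndarray]:
    """Generate a single-peak island DEM and its land mask.

    The DEM is a smooth radial peak of height ~``peak_height`` with
    low-amplitude seeded roughness; cells with elevation <= 0 are sea.
    Deterministic for a fixed seed.
    """
    n_rows, n_cols = params.shape
    if n_rows < 8 or n_cols < 8:
        raise ValueError("scene shape must be at least 8x8")
    rng = np.random.default_rng(params.seed)
    y = np.linspace(-1, 1, n_rows)[:, None]
    x = np.linspace(-1, 1, n_cols)[None, :]
    r = np.sqrt(x**2 + y**2)
    # Smooth cosine bell out to r=0.9, negative (sea floor) beyond.
    base = np.where(
        r < 0.9,
        params.peak_height * 0.5 * (1 + np.cos(np.pi * r / 0.9)),
        0.0,
    )
    depth = max(params.peak_height * 0.05, 30.0)
    elev = base - depth * np.clip((r - 0.82) / 0.18, 0.0, 1.0)
    rough = gaussian_filter(rng.normal(size=(n_rows, n_cols)), sigma=1.5)
    elev = elev + params.roughness * params.peak_height * rough
    land = elev > 0
    if not land.any():
        raise ValueError("degenerate scene: no land cells (peak too low)")
    if land.mean() < 0.25:
        raise ValueError("degenerate scene: less than 25% land cells")
    grid = GridMeta(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=params.origin_lon,
        origin_lat=params.origin_lat,
        resolution=params.resolution,
    )
    return DEMGrid(grid=grid, elevation=elev), land


def windward_field(grid: GridMeta) -> np.ndarray:
    """Linear west-to-east ramp in [0, 1] standing in for windward exposure."""
    if grid.n_cols == 1:
        return np.zeros(grid.shape)
    ramp = np.arange(grid.n_cols) / (grid.n_cols - 1)
    return np.broadcast_to(ramp, grid.shape).copy()


def _simulate_cube(
    dem: DEMGrid,
    land: np.ndarray,
    params: SceneParams,
    photoperiod: str,
    rng: np.random.Generator,
) -> LSTCube:
    layers = month_sequence(params.start_year, params.n_years)
    months = np.array([m for _, m in layers])
    seasonal = params.seasonal_amplitude * np.cos(
        2 * np.pi * (months - params.seasonal_phase) / 12
    )
    spatial = (
        params.sea_level_temp
        + params.lapse_rate * dem.elevation
        + params.windward_offset * windward_field(dem.grid)
    )
    if photoperiod == "Night":
        spatial = spatial - params.day_night_offset
    eta = rng.normal(0.0, params.slice_anomaly_sd, size=len(layers)) \
        if params.slice_anomaly_sd > 0 else np.zeros(len(layers))
    values = spatial[:, :, None] + (seasonal + eta)[None, None, :]
    if params.pixel_noise_sd > 0:
        values = values + rng.normal(0.0, params.pixel_noise_sd, size=values.shape)
    values = np.where(land[:, :, None], values, np.nan)
    return LSTCube(
        grid=dem.grid,
        photoperiod=photoperiod,
        layers=layers,
        values=values,
        land_mask=land,
    )


def simulate_lst(dem: DEMGrid, params: SceneParams, land: np.ndarray | None = None,
                 name: str = "Synthetica") -> IslandScene:
    """Simulate fully observed day and night cubes on a DEM.

    The returned scene is the ground truth; use :func:`simulate_cloud_mask`
    and :func:`apply_mask` to create gappy copies for imputer testing.
    """
    if land is None:
        land = dem.elevation > 0
    if land.shape != dem.grid.shape:
        raise ValueError("grid mismatch between DEM and land mask")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    day = _simulate_cube(dem, land, params, "Day", rng)
    night = _simulate_cube(dem, land, params, "Night", rng)
    return IslandScene(
        name=name,
        dem=dem,
        day=day,
        night=night,
        provenance={"generator": "islefill.synthetic", "params": asdict(params)},
    )


def simulate_cloud_mask(
    dem: DEMGrid,
    layers: list[tuple[int, int]],
    photoperiod: str,
    mparams: MissingnessParams,
) -> np.ndarray:
    """Draw a (rows, cols, layers) boolean cloud-gap mask.

    Missingness probability per cell and layer is
    ``logistic(b0 + b_elev*elev + b_day*[Day] + b_spring*[spring] + S_t)``
    where ``S_t`` is a smooth zero-mean spatial logit field redrawn per
    layer (white noise smoothed with a Gaussian kernel of width
    ``correlation_range`` and rescaled to ``spatial_field_sd``).
    """
    rng = np.random.default_rng(mparams.seed)
    n_rows, n_cols = dem.grid.shape
    out = np.zeros((n_rows, n_cols, len(layers)), dtype=bool)
    for t, (_, month) in enumerate(layers):
        logit = (
            mparams.intercept
            + mparams.b_elev * dem.elevation
            + (mparams.b_day if photoperiod == "Day" else 0.0)
            + (mparams.b_spring if month in SPRING_MONTHS else 0.0)
        )
        if mparams.spatial_field_sd > 0:
            raw = gaussian_filter(
                rng.normal(size=(n_rows, n_cols)), sigma=mparams.correlation_range
            )
            sd = raw.std()
            if sd > 0:
                logit = logit + raw * (mparams.spatial_field_sd / sd)
        out[:, :, t] = rng.random(size=(n_rows, n_cols)) < expit(logit)
    return out


def apply_mask(cube: LSTCube, mask: np.ndarray) -> LSTCube:
    """Return a copy of ``cube`` with masked cells set to missing."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube {cube.values.shape}"
        )
    out = cube.copy()
    out.values[mask] = np.nan
    return out


def make_scene(
    params: SceneParams | None = None,
    mparams: MissingnessParams | None = None,
    name: str = "Synthetica",
) -> tuple[IslandScene, IslandScene]:
    """Convenience: build (truth scene, gappy scene) in one call."""
    params = params or SceneParams()
    dem, land = make_dem(params)
    truth = simulate_lst(dem, params, land, name=name)
    if mparams is None:
        return truth, truth
    gappy_cubes = {}
    for pp in ("Day", "Night"):
        mp = MissingnessParams(**{**asdict(mparams),
                                  "seed": mparams.seed + (0 if pp == "Day" else 1)})
        mask = simulate_cloud_mask(dem, truth.day.layers, pp, mp)
        gappy_cubes[pp] = apply_mask(truth.cube(pp), mask)
    gappy = IslandScene(
        name=name,
        dem=dem,
        day=gappy_cubes["Day"],
        night=gappy_cubes["Night"],
        provenance={**truth.provenance, "missingness": asdict(mparams)},
    )
    return truth, gappy
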