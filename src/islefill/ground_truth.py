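"""Ground-truthing surface-temperature products against soil loggers.

Implements the Marion Island protocol: despiking of hourly logger
records, a solar day/night split, monthly day/night soil means, and the
paired comparison of gap-filled vs un-filled LST products against soil
temperatures (Pearson r, Mann-Whitney U with effect size, RMSE and
absolute-error summaries), with a 50% knockout applied before gap-filling
to balance the sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from islefill.gapfill import SubsetSpec, gapfill_cube
from islefill.grids import IslandScene
from islefill.validation import knockout_random

#: Refraction-adjusted solar zenith angle at sunrise/sunset, degrees.
SUNRISE_ZENITH = 90.833


@dataclass
class LoggerSeries:
    """One microclimate logger: site metadata plus an hourly record."""

    site: str
    lat: float
    lon: float
    elevation: float
    data: pd.Series  # DatetimeIndex (UTC) -> soil temperature, deg C

    def __post_init__(self) -> None:
        self.data = self.data.sort_index()
        if self.data.index.has_duplicates:
            raise ValueError(f"logger {self.site}: duplicate timestamps")


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------


def _solar_terms(day_of_year: np.ndarray, hours: np.ndarray):
    """NOAA general solar equations: equation of time (min), declination (rad)."""
    gamma = 2 * np.pi / 365.0 * (day_of_year - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    return eqtime, decl


def sunrise_sunset(
    day_of_year: int | np.ndarray, lat: float, lon: float,
    zenith: float = SUNRISE_ZENITH,
) -> tuple[np.ndarray, np.ndarray]:
    """Sunrise and sunset in UTC hours for a day-of-year at (lat, lon).

    Uses the solar-declination / hour-angle sunrise equation with a
    refraction-adjusted zenith.  Polar day clamps to (0, 24); polar night
    to an empty (12, 12) interval.
    """
    if abs(lat) > 90:
        raise ValueError("latitude out of range")
    doy = np.atleast_1d(np.asarray(day_of_year, dtype=float))
    eqtime, decl = _solar_terms(doy, np.full_like(doy, 12.0))
    phi = np.deg2rad(lat)
    cos_ha = (
        np.cos(np.deg2rad(zenith)) - np.sin(phi) * np.sin(decl)
    ) / (np.cos(phi) * np.cos(decl))
    ha = np.degrees(np.arccos(np.clip(cos_ha, -1.0, 1.0)))  # degrees
    solar_noon = 12.0 - lon / 15.0 - eqtime / 60.0
    sunrise = solar_noon - ha / 15.0
    sunset = solar_noon + ha / 15.0
    polar_day = cos_ha < -1.0
    polar_night = cos_ha > 1.0
    sunrise = np.where(polar_day, 0.0, np.where(polar_night, 12.0, sunrise))
    sunset = np.where(polar_day, 24.0, np.where(polar_night, 12.0, sunset))
    return sunrise, sunset


def day_night_split(timestamps, lat: float, lon: float) -> np.ndarray:
    """Label each UTC timestamp ``"Day"`` or ``"Night"`` at (lat, lon).

    A timestamp is Day iff it falls in ``[sunrise, sunset)`` of its own
    UTC date; polar day/night days are all-Day / all-Night.
    """
    idx = pd.DatetimeIndex(timestamps)
    doy = idx.dayofyear.to_numpy()
    hours = (
        idx.hour.to_numpy()
        + idx.minute.to_numpy() / 60.0
        + idx.second.to_numpy() / 3600.0
    )
    sunrise, sunset = sunrise_sunset(doy, lat, lon)
    is_day = (hours >= sunrise) & (hours < sunset)
    return np.where(is_day, "Day", "Night")


# ---------------------------------------------------------------------------
# logger conditioning
# ---------------------------------------------------------------------------


def despike(series: LoggerSeries, jump_threshold: float = 10.0) -> LoggerSeries:
    """Drop records following an hourly jump of ``jump_threshold`` deg C or more.

    Only consecutive records at most ~1 hour apart are compared; the later
    record of a spiking pair is removed (single pass).
    """
    data = series.data
    if len(data) < 2 or not np.isfinite(jump_threshold):
        return LoggerSeries(series.site, series.lat, series.lon,
                            series.elevation, data.copy())
    values = data.to_numpy(dtype=float)
    hours = data.index.astype("int64").to_numpy() / 3.6e12
    bad = np.zeros(len(data), dtype=bool)
    last = 0  # index of the last kept record
    for i in range(1, len(data)):
        jump = abs(values[i] - values[last])
        if jump >= jump_threshold and (hours[i] - hours[last]) <= 1.5:
            bad[i] = True
        else:
            last = i
    return LoggerSeries(series.site, series.lat, series.lon,
                        series.elevation, data[~bad].copy())


def monthly_soil_means(series: LoggerSeries, labels: np.ndarray) -> pd.DataFrame:
    """Mean monthly day and night soil temperature.

    ``labels`` is the per-record Day/Night labelling (from
    :func:`day_night_split`).  Returns a frame indexed by (year, month)
    with ``Day`` and ``Night`` columns; months without records are absent.
    """
    df = pd.DataFrame(
        {
            "temp": series.data.to_numpy(dtype=float),
            "photoperiod": labels,
            "year": series.data.index.year,
            "month": series.data.index.month,
        }
    )
    out = (
        df.groupby(["year", "month", "photoperiod"])["temp"]
        .mean()
        .unstack("photoperiod")
    )
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


@dataclass
class GroundComparison:
    """Agreement of one LST product with soil temperatures."""

    pearson_r: float
    n: int
    rmse: float
    median_abs_error: float
    iqr_abs_error: float
    mwu_U: float | None = None
    mwu_p: float | None = None
    effect_r: float | None = None
    abs_errors: np.ndarray = field(default=None, repr=False)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """Mann-Whitney U of sample ``a`` vs ``b``: (U, z, p, effect r).

    Normal approximation with tie correction, no continuity correction;
    the effect size is ``z / sqrt(n1 + n2)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(u), float(z), p, float(z / np.sqrt(n))


def compare_to_ground(
    lst_series: pd.Series,
    soil_series: pd.Series,
    exclude_below: float = 0.0,
    reference_abs_errors: np.ndarray | None = None,
) -> GroundComparison:
    """Score one LST product against aligned monthly soil temperatures.

    Months whose soil mean is below ``exclude_below`` are dropped (the
    sub-zero snow-insulation rule).  If ``reference_abs_errors`` is given
    (the other product's absolute errors), a Mann-Whitney U test between
    the two absolute-error samples is included with its effect size.
    """
    joined = pd.concat(
        {"lst": lst_series, "soil": soil_series}, axis=1, join="inner"
    ).dropna()
    joined = joined[joined["soil"] >= exclude_below]
    n = len(joined)
    if n < 10:
        raise ValueError(f"insufficient aligned pairs after exclusion (n={n})")
    lst = joined["lst"].to_numpy()
    soil = joined["soil"].to_numpy()
    err = lst - soil
    abs_err = np.abs(err)
    if np.ptp(lst) < 1e-15 or np.ptp(soil) < 1e-15:
        r = 1.0 if np.ptp(lst) < 1e-15 and np.ptp(soil) < 1e-15 else np.nan
    else:
        r = float(stats.pearsonr(lst, soil).statistic)
    out = GroundComparison(
        pearson_r=r,
        n=n,
        rmse=float(np.sqrt(np.mean(err**2))),
        median_abs_error=float(np.median(abs_err)),
        iqr_abs_error=float(np.subtract(*np.percentile(abs_err, [75, 25]))),
        abs_errors=abs_err,
    )
    if reference_abs_errors is not None:
        u, z, p, eff = mann_whitney_u(abs_err, np.asarray(reference_abs_errors))
        out.mwu_U, out.mwu_p, out.effect_r = u, p, eff
    return out


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


def _logger_cell(scene: IslandScene, logger: LoggerSeries) -> tuple[int, int]:
    """Nearest cell centre to a logger's coordinates."""
    grid = scene.dem.grid
    row = int(np.argmin(np.abs(grid.lats() - logger.lat)))
    col = int(np.argmin(np.abs(grid.lons() - logger.lon)))
    if not scene.day.land_mask[row, col]:
        land = np.argwhere(scene.day.land_mask)
        d2 = (land[:, 0] - row) ** 2 + (land[:, 1] - col) ** 2
        row, col = (int(v) for v in land[np.argmin(d2)])
    return row, col


def _cube_series(values: np.ndarray, layers, row: int, col: int) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(layers, names=["year", "month"])
    return pd.Series(values[row, col, :], index=idx)


def ground_truth_protocol(
    scene: IslandScene,
    loggers: list[LoggerSeries],
    knockout_fraction: float = 0.5,
    seed: int = 0,
    spec: SubsetSpec | None = None,
    exclude_below: float = 0.0,
    jump_threshold: float = 10.0,
) -> dict:
    """Run the full logger-comparison protocol for both photoperiods.

    Per photoperiod: knock out ``knockout_fraction`` of the LST
    observations, gap-fill, extract filled and un-filled monthly series at
    each logger cell, build despiked day/night monthly soil means, and
    compare both products to soil (pooled across sites).  Returns
    ``{photoperiod: {"filled": GroundComparison, "unfilled": GroundComparison}}``;
    the Mann-Whitney fields of each comparison use the other product's
    absolute errors as reference (so U values are complementary).
    """
    soil_monthly = {}
    for logger in loggers:
        clean = despike(logger, jump_threshold)
        labels = day_night_split(clean.data.index, clean.lat, clean.lon)
        soil_monthly[logger.site] = monthly_soil_means(clean, labels)

    out: dict[str, dict] = {}
    for photoperiod in ("Day", "Night"):
        cube = scene.cube(photoperiod)
        if knockout_fraction > 0:
            knock = knockout_random(cube, knockout_fraction, seed)
            thinned = knock.cube
        else:
            thinned = cube.copy()
        result = gapfill_cube(thinned, scene.dem, spec)
        pieces_filled, pieces_unfilled, pieces_soil = [], [], []
        for logger in loggers:
            if photoperiod not in soil_monthly[logger.site].columns:
                continue
            row, col = _logger_cell(scene, logger)
            soil = soil_monthly[logger.site][photoperiod].dropna()
            soil.index.names = ["year", "month"]
            filled = _cube_series(result.mean.values, cube.layers, row, col)
            unfilled = _cube_series(result.obs.values, cube.layers, row, col)
            pieces_filled.append(filled.rename(logger.site))
            pieces_unfilled.append(unfilled.rename(logger.site))
            pieces_soil.append(soil.rename(logger.site))
        lst_filled = pd.concat(pieces_filled, keys=range(len(pieces_filled)))
        lst_unfilled = pd.concat(pieces_unfilled, keys=range(len(pieces_unfilled)))
        soil_all = pd.concat(pieces_soil, keys=range(len(pieces_soil)))
        unfilled_cmp = compare_to_ground(lst_unfilled, soil_all, exclude_below)
        filled_cmp = compare_to_ground(
            lst_filled, soil_all, exclude_below,
            reference_abs_errors=unfilled_cmp.abs_errors,
        )
        unfilled_cmp = compare_to_ground(
            lst_unfilled, soil_all, exclude_below,
            reference_abs_errors=filled_cmp.abs_errors,
        )
        out[photoperiod] = {"filled": filled_cmp, "unfilled": unfilled_cmp}
    return out


def make_synthetic_loggers(
    scene: IslandScene,
    n_sites: int = 5,
    smoothing: float = 0.5,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> list[LoggerSeries]:
    """Hourly soil loggers derived from a scene's surface truth.

    Sites are spread along the elevational gradient.  Hourly soil
    temperature is the site's day/night surface value for that month
    (selected by the solar split), AR(1)-smoothed to emulate soil
    insulation, plus white noise.
    """
    rng = np.random.default_rng(seed)
    grid = scene.dem.grid
    land = np.argwhere(scene.day.land_mask)
    elevs = scene.dem.elevation[land[:, 0], land[:, 1]]
    order = np.argsort(elevs)
    picks = land[order[np.linspace(0, len(order) - 1, n_sites).astype(int)]]

    y0, m0 = scene.day.layers[0]
    y1, m1 = scene.day.layers[-1]
    index = pd.date_range(
        start=pd.Timestamp(year=y0, month=m0, day=1),
        end=pd.Timestamp(year=y1, month=m1, day=28, hour=23),
        freq="h",
    )
    month_of = {lab: i for i, lab in enumerate(scene.day.layers)}
    loggers = []
    for k, (row, col) in enumerate(picks):
        lat = grid.lats()[row]
        lon = grid.lons()[col]
        labels = day_night_split(index, lat, lon)
        keys = list(zip(index.year, index.month))
        t_idx = np.array([month_of[key] for key in keys])
        day_vals = scene.day.values[row, col, t_idx]
        night_vals = scene.night.values[row, col, t_idx]
        base = np.where(labels == "Day", day_vals, night_vals)
        noise = rng.normal(0, noise_sd, size=len(index))
        soil = np.empty_like(base)
        soil[0] = base[0]
        for i in range(1, len(base)):
            soil[i] = smoothing * soil[i - 1] + (1 - smoothing) * base[i] + \
                (1 - smoothing) * noise[i]
        loggers.append(
            LoggerSeries(
                site=f"site{k}",
                lat=float(lat),
                lon=float(lon),
                elevation=float(scene.dem.elevation[row, col]),
                data=pd.Series(soil, index=index),
            )
        )
    return loggers


def loggers_from_csv(path) -> list[LoggerSeries]:
    """Read loggers from the harmonized CSV schema.

    Columns: ``site,lat,lon,elevation_m,timestamp_iso8601,soil_temp_c``.
    """
    df = pd.read_csv(path, parse_dates=["timestamp_iso8601"])
    out = []
    for site, g in df.groupby("site"):
        out.append(
            LoggerSeries(
                site=str(site),
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                elevation=float(g["elevation_m"].iloc[0]),
                data=pd.Series(
                    g["soil_temp_c"].to_numpy(dtype=float),
                    index=pd.DatetimeIndex(g["timestamp_iso8601"]),
                ),
            )
        )
    return out
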