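"""MODIS-style conditioning of raw LST stacks.

Digital-number scaling, per-island quantile outlier exclusion, 8-day to
monthly aggregation, bilinear DEM resampling, and missing-data accounting
with the gap-fill eligibility rule.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from islefill.grids import DEMGrid, GridMeta, LSTCube

#: MODIS LST digital-number scale factor (DN -> Kelvin).
MODIS_SCALE = 0.02
#: Valid digital-number range of the MODIS LST product.
MODIS_VALID_RANGE = (7500, 65535)
KELVIN_OFFSET = 273.15


def scale_to_celsius(raw_dn: np.ndarray) -> np.ndarray:
    """Convert MODIS digital numbers to deg C (``raw*0.02 - 273.15``).

    Digital numbers outside the valid range become missing (nan).
    """
    raw = np.asarray(raw_dn)
    if not np.issubdtype(raw.dtype, np.integer):
        raise TypeError("digital numbers must be an integer array")
    lo, hi = MODIS_VALID_RANGE
    celsius = raw * MODIS_SCALE - KELVIN_OFFSET
    return np.where((raw >= lo) & (raw <= hi), celsius, np.nan)


def quantile_filter(
    cube: LSTCube, central_mass: float = 0.9999
) -> tuple[LSTCube, int]:
    """Drop values outside the central ``central_mass`` quantile interval.

    Quantiles are empirical (linear interpolation of order statistics)
    over all non-missing values of the cube; values strictly outside
    ``[Q((1-m)/2), Q(1-(1-m)/2)]`` are set to missing.  Returns the
    filtered cube and the number of values removed.
    """
    if not 0.5 < central_mass <= 1.0:
        raise ValueError("central_mass must be in (0.5, 1]")
    finite = np.isfinite(cube.values)
    vals = cube.values[finite]
    if vals.size < 2:
        raise ValueError("cube must contain at least 2 non-missing values")
    tail = (1.0 - central_mass) / 2.0
    q_lo, q_hi = np.quantile(vals, [tail, 1.0 - tail])
    out = cube.copy()
    bad = finite & ((cube.values < q_lo) | (cube.values > q_hi))
    out.values[bad] = np.nan
    return out, int(bad.sum())


@dataclass
class CompositeCube:
    """An 8-day composite stack: like a cube, but layers carry start dates."""

    grid: GridMeta
    photoperiod: str
    dates: list[dt.date]
    values: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols, len(self.dates)):
            raise ValueError("values shape does not match grid/dates")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("composite start dates must be strictly increasing")


def monthly_mean(eight_day: CompositeCube) -> LSTCube:
    """Average 8-day composites into monthly layers.

    A composite contributes to the calendar month containing its start
    date.  Months (between the first and last composite month, inclusive)
    with no contributing finite value at a cell are missing there.
    """
    keys = [d.year * 12 + (d.month - 1) for d in eight_day.dates]
    first, last = keys[0], keys[-1]
    layers = [(k // 12, k % 12 + 1) for k in range(first, last + 1)]
    n_rows, n_cols, _ = eight_day.values.shape
    out = np.full((n_rows, n_cols, len(layers)), np.nan)
    keys_arr = np.asarray(keys)
    for t, key in enumerate(range(first, last + 1)):
        sel = eight_day.values[:, :, keys_arr == key]
        if sel.shape[2]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[:, :, t] = np.nanmean(sel, axis=2)
    out = np.where(eight_day.land_mask[:, :, None], out, np.nan)
    return LSTCube(
        grid=eight_day.grid,
        photoperiod=eight_day.photoperiod,
        layers=layers,
        values=out,
        land_mask=eight_day.land_mask,
    )


def resample_bilinear(dem_fine: DEMGrid, target: GridMeta) -> DEMGrid:
    """Bilinearly resample a fine DEM onto a coarser target grid.

    Each target cell centre takes the bilinear interpolation of the four
    surrounding source cell centres; target centres must lie within the
    source centre extent.
    """
    src_lats = dem_fine.grid.lats()  # decreasing
    src_lons = dem_fine.grid.lons()
    tgt_lats = target.lats()
    tgt_lons = target.lons()
    if (
        tgt_lats.max() > src_lats.max() + 1e-12
        or tgt_lats.min() < src_lats.min() - 1e-12
        or tgt_lons.min() < src_lons.min() - 1e-12
        or tgt_lons.max() > src_lons.max() + 1e-12
    ):
        raise ValueError("target grid extent outside source DEM coverage")
    interp = RegularGridInterpolator(
        (src_lats[::-1], src_lons),
        dem_fine.elevation[::-1, :],
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    lat_g, lon_g = np.meshgrid(tgt_lats, tgt_lons, indexing="ij")
    pts = np.column_stack([lat_g.ravel(), lon_g.ravel()])
    out = interp(pts).reshape(target.shape)
    return DEMGrid(grid=target, elevation=out)


def missing_profile(cube: LSTCube) -> tuple[np.ndarray, float]:
    """Per-land-cell missing counts and the overall percentage available.

    Counts are over land cells only (nan elsewhere); availability is
    ``100 * observed land cell-layers / (land cells * layers)``.
    """
    missing = ~np.isfinite(cube.values)
    counts = missing.sum(axis=2).astype(float)
    counts[~cube.land_mask] = np.nan
    n_land = int(cube.land_mask.sum())
    total = n_land * cube.n_layers
    if total == 0:
        return counts, 0.0
    observed = total - int(np.nansum(counts[cube.land_mask]))
    return counts, 100.0 * observed / total


def eligible_for_gapfill(cube: LSTCube, threshold: float = 0.5) -> bool:
    """True iff the cube's missing fraction does not exceed ``threshold``.

    Islands with *more than* 50% missing monthly observations are not
    gap-filled; exactly 50% missing remains eligible.
    """
    _, pct_available = missing_profile(cube)
    missing_frac = 1.0 - pct_available / 100.0
    return missing_frac <= threshold + 1e-12
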