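"""Domain types for island raster scenes.

Conventions used throughout the package:

- coordinates refer to cell centres;
- row 0 is the northernmost row (latitude decreases with row index);
- all indexing is 0-based;
- the missing-value sentinel is ``numpy.nan``;
- cube layers are calendar months labelled ``YYYYMM`` and strictly
  increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EPSG identifier of the geographic WGS84 system all grids live in.
WGS84 = "EPSG:4326"

#: Default grid resolution in decimal degrees (~1 km).
DEFAULT_RESOLUTION = 0.0083

#: Default physical plausibility range for surface temperatures, in deg C.
PHYSICAL_RANGE = (-130.0, 70.0)

PHOTOPERIODS = ("Day", "Night")
DATA_TYPES = ("mean", "upperCI", "lowerCI", "obs")


def month_label(year: int, month: int) -> str:
    """Render a (year, month) pair as a ``YYYYMM`` label."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return f"{year:04d}{month:02d}"


def parse_label(label: str | int) -> tuple[int, int]:
    """Parse a ``YYYYMM`` label into a (year, month) pair."""
    s = str(int(label))
    if len(s) != 6:
        raise ValueError(f"not a YYYYMM label: {label!r}")
    year, month = int(s[:4]), int(s[4:])
    if not 1 <= month <= 12:
        raise ValueError(f"not a YYYYMM label: {label!r}")
    return year, month


def month_sequence(start_year: int, n_years: int) -> list[tuple[int, int]]:
    """All (year, month) pairs for ``n_years`` whole years from January."""
    return [(start_year + y, m) for y in range(n_years) for m in range(1, 13)]


def shift_month(year: int, month: int, months: int) -> tuple[int, int]:
    """Shift a calendar (year, month) by a signed number of months."""
    idx = year * 12 + (month - 1) + months
    return idx // 12, idx % 12 + 1


@dataclass(frozen=True)
class GridMeta:
    """Geographic metadata of a regular lat/lon grid (WGS84, cell centres)."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    resolution: float = DEFAULT_RESOLUTION
    crs_id: str = WGS84

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.crs_id != WGS84:
            raise ValueError(f"unsupported CRS {self.crs_id!r}; expected {WGS84!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.origin_lon + self.resolution * np.arange(self.n_cols)

    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, north (row 0) to south."""
        return self.origin_lat - self.resolution * np.arange(self.n_rows)

    def congruent(self, other: "GridMeta") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.resolution, other.resolution)
        )


def _require_congruent(a: GridMeta, b: GridMeta, what: str) -> None:
    if not a.congruent(b):
        raise ValueError(f"grid mismatch: {what}")


@dataclass
class LSTCube:
    """A lat x lon x month stack of land-surface temperatures in deg C.

    ``values`` has shape ``(n_rows, n_cols, n_layers)`` with ``nan`` as the
    missing sentinel.  ``layers`` holds (year, month) pairs in strictly
    increasing calendar order; sea cells (``land_mask`` false) are missing
    in every layer.
    """

    grid: GridMeta
    photoperiod: str
    layers: list[tuple[int, int]]
    values: np.ndarray
    land_mask: np.ndarray
    physical_range: tuple[float, float] = PHYSICAL_RANGE

    def __post_init__(self) -> None:
        if self.photoperiod not in PHOTOPERIODS:
            raise ValueError(f"unknown photoperiod {self.photoperiod!r}")
        self.layers = [tuple(lab) for lab in self.layers]
        self.values = np.asarray(self.values, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        expected = (self.grid.n_rows, self.grid.n_cols, len(self.layers))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected} from grid/layers"
            )
        if self.land_mask.shape != self.grid.shape:
            raise ValueError("land_mask shape does not match grid")

    # -- properties ----------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def labels(self) -> list[str]:
        """Layer labels rendered YYYYMM."""
        return [month_label(y, m) for y, m in self.layers]

    def layer_index(self, label: str | int | tuple[int, int]) -> int:
        """Index of a layer given its YYYYMM label or (year, month) pair."""
        key = tuple(label) if isinstance(label, (tuple, list)) else parse_label(label)
        try:
            return self.layers.index(key)
        except ValueError:
            raise KeyError(f"layer {label!r} absent from cube") from None

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check the cube invariants, raising ``ValueError`` on violation."""
        keys = [y * 12 + m for y, m in self.layers]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("layer labels must be strictly increasing")
        lo, hi = self.physical_range
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"values outside physical range [{lo}, {hi}] deg C present"
            )
        if np.isfinite(self.values[~self.land_mask]).any():
            raise ValueError("sea cells must be missing in every layer")

    # -- helpers -------------------------------------------------------

    def copy(self) -> "LSTCube":
        return LSTCube(
            grid=self.grid,
            photoperiod=self.photoperiod,
            layers=list(self.layers),
            values=self.values.copy(),
            land_mask=self.land_mask.copy(),
            physical_range=self.physical_range,
        )

    def observed_mask(self) -> np.ndarray:
        """Boolean (rows, cols, layers) mask of non-missing values."""
        return np.isfinite(self.values)

    def n_observed(self) -> int:
        return int(self.observed_mask().sum())


@dataclass
class DEMGrid:
    """Elevation in metres on the same grid convention as :class:`LSTCube`."""

    grid: GridMeta
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != self.grid.shape:
            raise ValueError("elevation shape does not match grid")

    def validate_against(self, cube: LSTCube) -> None:
        _require_congruent(self.grid, cube.grid, "DEM vs cube")
        if not np.isfinite(self.elevation[cube.land_mask]).all():
            raise ValueError("elevation must be finite on land cells")


@dataclass
class IslandScene:
    """DEM plus day and night LST cubes for one island."""

    name: str
    dem: DEMGrid
    day: LSTCube
    night: LSTCube
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_congruent(self.day.grid, self.night.grid, "day vs night cubes")
        _require_congruent(self.dem.grid, self.day.grid, "DEM vs cubes")
        if not np.array_equal(self.day.land_mask, self.night.land_mask):
            raise ValueError("day and night cubes must share a land mask")
        if self.day.layers != self.night.layers:
            raise ValueError("day and night cubes must share layer labels")

    def cube(self, photoperiod: str) -> LSTCube:
        if photoperiod == "Day":
            return self.day
        if photoperiod == "Night":
            return self.night
        raise ValueError(f"unknown photoperiod {photoperiod!r}")


@dataclass
class GapfillResult:
    """Output of gap-filling one cube: four congruent cubes + failure mask.

    ``mean`` carries observations where observed and clipped predictions
    where filled; ``lower_ci``/``upper_ci`` are populated only for filled
    cells and are *not* clipped; ``obs`` is the unfilled input; ``failed``
    marks attempted cells for which no prediction could be made.
    """

    mean: LSTCube
    lower_ci: LSTCube
    upper_ci: LSTCube
    obs: LSTCube
    failed: np.ndarray
    clip_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.failed = np.asarray(self.failed, dtype=bool)
        if self.failed.shape != self.obs.values.shape:
            raise ValueError("failure mask shape does not match cube")

    def validate(self) -> None:
        obs_ok = np.isfinite(self.obs.values)
        if not np.array_equal(
            self.mean.values[obs_ok], self.obs.values[obs_ok]
        ):
            raise ValueError("mean must equal obs where observed")
        if np.isfinite(self.lower_ci.values[obs_ok]).any():
            raise ValueError("CIs must be missing where observed")
        filled = ~obs_ok & np.isfinite(self.mean.values)
        lo, hi = self.clip_range
        m = self.mean.values[filled]
        if m.size and (m.min() < lo - 1e-12 or m.max() > hi + 1e-12):
            raise ValueError("filled means must lie within the clip range")
        bad = (self.lower_ci.values[filled] > m + 1e-9) | (
            self.upper_ci.values[filled] < m - 1e-9
        )
        if bad.any():
            raise ValueError("CI ordering violated on filled cells")
        if np.isfinite(self.mean.values[self.failed]).any():
            raise ValueError("failed cells must be missing in mean")

    def cube_for(self, dtype: str) -> LSTCube:
        mapping = {
            "mean": self.mean,
            "upperCI": self.upper_ci,
            "lowerCI": self.lower_ci,
            "obs": self.obs,
        }
        try:
            return mapping[dtype]
        except KeyError:
            raise ValueError(f"unknown data type {dtype!r}") from None


def output_name(island: str, photoperiod: str, dtype: str, ext: str) -> str:
    """File name per the ``<island>_<photoperiod>_1km_mon_<dtype>.<ext>`` convention."""
    if photoperiod not in PHOTOPERIODS:
        raise ValueError(f"unknown photoperiod {photoperiod!r}")
    if dtype not in DATA_TYPES:
        raise ValueError(f"unknown data type {dtype!r}")
    return f"{island}_{photoperiod}_1km_mon_{dtype}.{ext.lstrip('.')}"
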