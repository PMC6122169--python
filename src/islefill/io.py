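"""Reading and writing cube / DEM stacks as netCDF or GeoTIFF.

netCDF files use a single temperature variable with a YYYYMM-labelled time
dimension and CF-style ``lat``/``lon`` coordinate variables (classic
NetCDF3 via the scipy backend, so no compiled netCDF library is needed).
GeoTIFF stacks are written with one page per month, minimal GeoTIFF
georeferencing tags for WGS84 and a JSON sidecar description carrying the
band labels and land mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from islefill.grids import WGS84, DEMGrid, GridMeta, LSTCube, parse_label

_LST_VAR = "lst"
_FILL = -9999.0

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735


def _format_from_path(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("netcdf", "geotiff"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".nc":
        return "netcdf"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer format from {path!r}; pass format=...")


def _check_labels(labels: list[str]) -> list[tuple[int, int]]:
    pairs = [parse_label(lab) for lab in labels]
    keys = [y * 12 + m for y, m in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicated band labels")
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise ValueError("band labels not strictly increasing")
    return pairs


# ---------------------------------------------------------------------------
# netCDF
# ---------------------------------------------------------------------------


def _cube_to_dataset(cube: LSTCube) -> xr.Dataset:
    ds = xr.Dataset(
        {
            _LST_VAR: (
                ("lat", "lon", "time"),
                cube.values,
                {"units": "degC", "long_name": "land surface temperature"},
            ),
            "land_mask": (("lat", "lon"), cube.land_mask.astype(np.int8)),
        },
        coords={
            "lat": ("lat", cube.grid.lats(), {"units": "degrees_north"}),
            "lon": ("lon", cube.grid.lons(), {"units": "degrees_east"}),
            "time": ("time", np.array([int(s) for s in cube.labels], dtype=np.int32),
                     {"long_name": "month", "format": "YYYYMM"}),
        },
        attrs={"crs": WGS84, "photoperiod": cube.photoperiod,
               "resolution": cube.grid.resolution},
    )
    return ds


def _dataset_to_cube(ds: xr.Dataset, photoperiod: str | None) -> LSTCube:
    labels = [str(int(t)) for t in ds["time"].values]
    layers = _check_labels(labels)
    lats = np.asarray(ds["lat"].values, dtype=float)
    lons = np.asarray(ds["lon"].values, dtype=float)
    res = float(ds.attrs.get("resolution", abs(lats[1] - lats[0]) if lats.size > 1 else 0.0083))
    grid = GridMeta(
        n_rows=lats.size, n_cols=lons.size,
        origin_lon=float(lons[0]), origin_lat=float(lats[0]), resolution=res,
    )
    values = np.asarray(ds[_LST_VAR].values, dtype=float)
    values[values == _FILL] = np.nan
    if "land_mask" in ds:
        land = np.asarray(ds["land_mask"].values).astype(bool)
    else:
        land = np.isfinite(values).any(axis=2)
    pp = photoperiod or ds.attrs.get("photoperiod")
    if pp is None:
        raise ValueError("photoperiod not recorded in file; pass photoperiod=")
    return LSTCube(grid=grid, photoperiod=pp, layers=layers, values=values, land_mask=land)


# ---------------------------------------------------------------------------
# GeoTIFF
# ---------------------------------------------------------------------------


def _geotiff_tags(grid: GridMeta):
    res = grid.resolution
    # Tie the raster's top-left *corner* to the corner of the origin cell.
    west = grid.origin_lon - res / 2
    north = grid.origin_lat + res / 2
    # Minimal GeoTIFF key directory: geographic model, pixel-is-area, EPSG:4326.
    keys = [1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326]
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)),
    ]


def _write_geotiff(path: Path, data: np.ndarray, grid: GridMeta, meta: dict) -> None:
    description = json.dumps(meta)
    with tifffile.TiffWriter(path) as tif:
        pages = data if data.ndim == 3 else data[None]
        for i, page in enumerate(pages):
            tif.write(
                page.astype(np.float64),
                description=description if i == 0 else None,
                extratags=_geotiff_tags(grid) if i == 0 else (),
                contiguous=False,
            )


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridMeta, dict]:
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description
    if not desc:
        raise ValueError(f"{path}: missing stack metadata description")
    meta = json.loads(desc)
    grid = GridMeta(**meta["grid"])
    data = np.stack(pages, axis=0)
    return data, grid, meta


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def write_cube(cube: LSTCube, path: str | Path, format: str | None = None) -> None:
    """Write a cube to ``path`` as netCDF (``.nc``) or GeoTIFF (``.tif``).

    Files round-trip bit-identically through :func:`read_cube` (values,
    missingness, band labels, grid metadata).
    """
    cube.validate()
    fmt = _format_from_path(path, format)
    path = Path(path)
    if fmt == "netcdf":
        ds = _cube_to_dataset(cube)
        ds.to_netcdf(path, engine="scipy")
    else:
        meta = {
            "grid": {
                "n_rows": cube.grid.n_rows,
                "n_cols": cube.grid.n_cols,
                "origin_lon": cube.grid.origin_lon,
                "origin_lat": cube.grid.origin_lat,
                "resolution": cube.grid.resolution,
            },
            "photoperiod": cube.photoperiod,
            "labels": cube.labels,
            "land_mask": [int(v) for v in cube.land_mask.ravel()],
            "crs": WGS84,
        }
        # pages are (rows, cols) per month
        _write_geotiff(path, np.moveaxis(cube.values, 2, 0), cube.grid, meta)


def read_cube(path: str | Path, photoperiod: str | None = None) -> LSTCube:
    """Read a cube written by :func:`write_cube` (format inferred from suffix)."""
    fmt = _format_from_path(path, None)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            cube = _dataset_to_cube(ds.load(), photoperiod)
        return cube
    data, grid, meta = _read_geotiff(path)
    layers = _check_labels(meta["labels"])
    land = np.asarray(meta["land_mask"], dtype=bool).reshape(grid.shape)
    pp = photoperiod or meta.get("photoperiod")
    return LSTCube(
        grid=grid,
        photoperiod=pp,
        layers=layers,
        values=np.moveaxis(data, 0, 2),
        land_mask=land,
    )


def write_dem(dem: DEMGrid, path: str | Path) -> None:
    """Write a DEM as a single-band GeoTIFF."""
    meta = {
        "grid": {
            "n_rows": dem.grid.n_rows,
            "n_cols": dem.grid.n_cols,
            "origin_lon": dem.grid.origin_lon,
            "origin_lat": dem.grid.origin_lat,
            "resolution": dem.grid.resolution,
        },
        "kind": "dem",
        "crs": WGS84,
    }
    _write_geotiff(Path(path), dem.elevation, dem.grid, meta)


def read_dem(path: str | Path) -> DEMGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, grid, _ = _read_geotiff(path)
    return DEMGrid(grid=grid, elevation=data[0] if data.ndim == 3 else data)
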