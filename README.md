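# islefill

Elevation-aware spatio-temporal gap-filling of monthly land-surface-temperature
(LST) raster time series, with the full technical-validation toolkit:
knockout cross-validation, support–error analysis, spatial-autocorrelation
and missingness diagnostics, and ground-truthing against microclimate
loggers. Everything runs on synthetic island scenes, so no satellite
downloads are required to exercise or test the pipeline.

## What it does

For every missing land cell-month in a cube of monthly LSTs, the gap-filler:

1. extracts a spatio-temporal subset — by default an 11×11 spatial window
   crossed with the previous/same/next month over a five-year span
   (≤ 121 cells × 15 time slices);
2. estimates the target cell's quantile level from its rank history within
   the subset;
3. fits linear quantile regressions (exact pinball-loss minimisation via
   linear programming) of value on the time-slice anomaly and cell
   **elevation**, producing a point prediction plus 95% interval estimates;
4. clips the point prediction to the island's observed temperature range
   (intervals are deliberately left unclipped);
5. records a failure instead of a prediction when fewer than `n_min`
   observed neighbours support the fit.

Cubes with more than 50% missing values are refused, mirroring the
eligibility rule of the underlying protocol.

## Layout

| module | contents |
| --- | --- |
| `islefill.grids` | `GridMeta`, `LSTCube`, `DEMGrid`, `IslandScene`, `GapfillResult`, file-naming convention |
| `islefill.io` | netCDF (scipy backend) and GeoTIFF stack read/write with `YYYYMM` band labels |
| `islefill.synthetic` | island DEM + day/night LST simulation, cloud-gap missingness generator |
| `islefill.preprocess` | digital-number scaling, quantile outlier filter, 8-day→monthly means, bilinear DEM resampling, eligibility |
| `islefill.quantreg` | exact quantile regression (dual LP) + brute-force oracle |
| `islefill.gapfill` | subset extraction, support counting, prediction, clipping, cube orchestration |
| `islefill.validation` | random/clustered knockouts, error statistics, support–error median regression, Moran's I, logit & negative-binomial GLMs |
| `islefill.ground_truth` | logger despiking, solar day/night split, monthly soil means, product-vs-soil comparison protocol |
| `islefill.reports` | per-island summary statistics and the end-to-end pipeline |
| `islefill.cli` | the `islefill` command |

## CLI

```sh
# generate a synthetic scene (DEM + truth + gappy cubes + provenance)
islefill simulate --config scene.yaml --seed 1 --out scene_dir/

# gap-fill one cube; writes <island>_<photoperiod>_1km_mon_<dtype>.nc x4
islefill fill --in scene_dir/obs_day.nc --dem scene_dir/dem.tif \
    --out-prefix Synthetica_Day --out-dir out/ --radius 5 --nmin 10

# knockout validation scenarios (Table-2/3-shaped reports)
islefill validate --scene scene_dir/ --mode clustered \
    --fractions 5,10,20,30,40,50 --seed 17 --out report/

# compare filled vs un-filled products against soil loggers
islefill groundtruth --scene scene_dir/ --knockout 0.5 --seed 3 --out gt.json

# everything end to end, reproducibly
islefill pipeline --config pipeline.yaml --seed 9 --out run/
```

A minimal `scene.yaml`:

```yaml
island: Synthetica
scene:
  shape: [24, 24]
  n_years: 3
  peak_height: 1200.0
  lapse_rate: -0.0065
  missingness:
    intercept: -2.5
    b_elev: 0.0015
```

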