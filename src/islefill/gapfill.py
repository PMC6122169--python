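"""Elevation-aware spatio-temporal quantile-regression gap-filling.

For every missing land cell-layer, a spatio-temporal subset is extracted
(an ``(2r+1) x (2r+1)`` spatial window crossed with neighbouring months
and years), a target quantile level is estimated from the target cell's
rank history within the subset, and a linear quantile regression on the
slice anomaly and cell elevation predicts the missing value with 95%
interval estimates.  Point predictions are clipped to the island's
observed range; interval estimates are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from islefill.grids import DEMGrid, GapfillResult, LSTCube, shift_month
from islefill.preprocess import eligible_for_gapfill
from islefill.quantreg import fit_quantile

_TAU_TRUNC = (0.05, 0.95)


@dataclass(frozen=True)
class SubsetSpec:
    """Search-strategy parameters of the gap-filler.

    Defaults follow the published strategy: an 11x11 spatial window
    (radius 5), the previous/same/next month, and the two previous and
    next years, giving at most 121 cells x 15 time slices per subset.
    """

    spatial_radius: int = 5
    month_offsets: tuple[int, ...] = (-1, 0, 1)
    year_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)
    n_min: int = 10
    tau_ci: tuple[float, float] = (0.025, 0.975)
    clip_range: tuple[float, float] | None = None
    predict_at: str = "tau_star"  # or "median"

    def __post_init__(self) -> None:
        if self.spatial_radius < 1:
            raise ValueError("spatial_radius must be at least 1")
        if not all(0.0 < t < 1.0 for t in self.tau_ci):
            raise ValueError("tau_ci levels must lie in (0, 1)")
        if self.clip_range is not None and self.clip_range[0] > self.clip_range[1]:
            raise ValueError("clip_range min must not exceed max")
        # 3 regression coefficients at most; guard degenerate fits
        if self.n_min < 4:
            raise ValueError("n_min must be at least coefficients + 1 = 4")
        if self.predict_at not in ("tau_star", "median"):
            raise ValueError("predict_at must be 'tau_star' or 'median'")


@dataclass
class Subset:
    """One target's spatio-temporal neighbourhood, shaped cells x slices."""

    values: np.ndarray  # (n_cells, n_slices), nan-missing; target entry nan
    elevations: np.ndarray  # (n_cells,)
    slice_labels: list[tuple[int, int]]
    target_cell: int  # row index into values/elevations
    target_slice: int  # column index into values
    cell_rows: np.ndarray
    cell_cols: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]


def compute_clip_range(cube: LSTCube) -> tuple[float, float]:
    """(min, max) of all observed values of a per-island, per-photoperiod cube."""
    finite = cube.values[np.isfinite(cube.values)]
    if finite.size == 0:
        raise ValueError("cannot compute clip range of an all-missing cube")
    return float(finite.min()), float(finite.max())


def _slice_layer_indices(
    cube: LSTCube, layer_idx: int, spec: SubsetSpec
) -> tuple[list[int], int]:
    """Cube layer indices of the subset slices, plus the target's position.

    Month offsets wrap across year boundaries (Dec+1 -> Jan of next year);
    slices whose (year, month) is absent from the cube are dropped.
    """
    y0, m0 = cube.layers[layer_idx]
    lookup = {lab: i for i, lab in enumerate(cube.layers)}
    wanted = []
    for yo in sorted(spec.year_offsets):
        for mo in sorted(spec.month_offsets):
            lab = shift_month(y0 + yo, m0, mo)
            idx = lookup.get(lab)
            if idx is not None and idx not in wanted:
                wanted.append(idx)
    wanted.sort()
    try:
        target_pos = wanted.index(layer_idx)
    except ValueError:
        # target month excluded by an exotic offset set; append it
        wanted.append(layer_idx)
        wanted.sort()
        target_pos = wanted.index(layer_idx)
    return wanted, target_pos


def extract_subset(
    cube: LSTCube,
    dem: DEMGrid,
    cell: tuple[int, int],
    layer,
    spec: SubsetSpec | None = None,
) -> Subset:
    """Extract the spatio-temporal search subset for one (cell, layer).

    ``layer`` may be a YYYYMM label or a (year, month) pair.  The window
    is truncated (not wrapped) at grid edges; year offsets truncate at the
    series edges.  The target entry is set missing — it is the value being
    predicted.
    """
    spec = spec or SubsetSpec()
    row, col = cell
    if not cube.land_mask[row, col]:
        raise ValueError(f"cell {cell} is not a land cell")
    layer_idx = layer if isinstance(layer, (int, np.integer)) and not _looks_like_label(layer) \
        else cube.layer_index(layer)
    r = spec.spatial_radius
    r0, r1 = max(0, row - r), min(cube.grid.n_rows, row + r + 1)
    c0, c1 = max(0, col - r), min(cube.grid.n_cols, col + r + 1)
    slice_idx, target_pos = _slice_layer_indices(cube, layer_idx, spec)

    block = cube.values[r0:r1, c0:c1, :][:, :, slice_idx]
    n_r, n_c, n_s = block.shape
    values = block.reshape(n_r * n_c, n_s).copy()
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    cell_rows, cell_cols = rows.ravel(), cols.ravel()
    target_cell = int(np.flatnonzero((cell_rows == row) & (cell_cols == col))[0])
    values[target_cell, target_pos] = np.nan
    return Subset(
        values=values,
        elevations=dem.elevation[r0:r1, c0:c1].ravel(),
        slice_labels=[cube.layers[i] for i in slice_idx],
        target_cell=target_cell,
        target_slice=target_pos,
        cell_rows=cell_rows,
        cell_cols=cell_cols,
    )


def _looks_like_label(layer) -> bool:
    return isinstance(layer, (int, np.integer)) and int(layer) >= 100001


def count_support(subset: Subset) -> int:
    """Number of observed entries in the subset (target excluded)."""
    return int(np.isfinite(subset.values).sum())


def estimate_target_quantile(subset: Subset) -> float:
    """Estimate the target cell's quantile level from its rank history.

    For each slice where the target cell is observed, the target's
    normalized mid-rank (Hazen, ``(R - 0.5)/n``) among that slice's
    observed cells is computed; the estimate is their mean, truncated to
    [0.05, 0.95], with a fallback of 0.5 when the target is never
    observed.
    """
    taus = []
    for s in range(subset.n_slices):
        col = subset.values[:, s]
        target_val = col[subset.target_cell]
        if not np.isfinite(target_val):
            continue
        obs = col[np.isfinite(col)]
        n = obs.size
        # mid-rank: average of strict rank and tie-inclusive rank
        rank = 0.5 * ((obs < target_val).sum() + (obs <= target_val).sum() + 1)
        taus.append((rank - 0.5) / n)
    if not taus:
        return 0.5
    lo, hi = _TAU_TRUNC
    return float(np.clip(np.mean(taus), lo, hi))


def _design(subset: Subset) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Build the regression design over observed entries.

    Columns: intercept, slice anomaly (slice mean minus grand mean of the
    subset's observations; 0 for empty slices), elevation.  Collinear
    (constant) non-intercept columns are dropped.  Returns (X, y, x_target,
    kept column ids).
    """
    finite = np.isfinite(subset.values)
    obs_cell, obs_slice = np.nonzero(finite)
    y = subset.values[obs_cell, obs_slice]
    grand = y.mean()
    slice_anom = np.zeros(subset.n_slices)
    for s in range(subset.n_slices):
        col = subset.values[finite[:, s], s]
        if col.size:
            slice_anom[s] = col.mean() - grand
    cols = [
        np.ones(y.size),
        slice_anom[obs_slice],
        subset.elevations[obs_cell],
    ]
    x_target_full = np.array(
        [1.0, slice_anom[subset.target_slice], subset.elevations[subset.target_cell]]
    )
    keep = [0] + [
        j for j in (1, 2) if np.ptp(cols[j]) > 1e-12
    ]
    X = np.column_stack([cols[j] for j in keep])
    return X, y, x_target_full[keep], keep


@dataclass
class Prediction:
    """A successful gap-fill prediction for one cell-layer."""

    mean: float
    lower: float
    upper: float
    tau_star: float
    support: int


def qr_predict(
    subset: Subset, tau_star: float, spec: SubsetSpec | None = None
) -> Prediction | None:
    """Quantile-regression prediction of the target value, or None on failure.

    Fails (returns None) when the subset's support is below ``spec.n_min``
    — including the zero-support case where a month is missing across all
    neighbouring cells.  Interval estimates come from direct fits at the
    ``tau_ci`` levels and may cross the point fit in degenerate designs;
    ordering is restored by widening the interval, never by moving the
    point prediction.
    """
    spec = spec or SubsetSpec()
    support = count_support(subset)
    if support < spec.n_min:
        return None
    X, y, x_target, _ = _design(subset)
    if np.ptp(y) < 1e-12:
        c = float(y[0])
        return Prediction(mean=c, lower=c, upper=c, tau_star=tau_star, support=support)
    tau_point = tau_star if spec.predict_at == "tau_star" else 0.5
    preds = {}
    for tau in (tau_point, *spec.tau_ci):
        beta = fit_quantile(X, y, tau)
        preds[tau] = float(x_target @ beta)
    mean = preds[tau_point]
    lower = min(preds[spec.tau_ci[0]], mean)
    upper = max(preds[spec.tau_ci[1]], mean)
    return Prediction(mean=mean, lower=lower, upper=upper,
                      tau_star=tau_star, support=support)


def clip_mean(value: float, clip_range: tuple[float, float]) -> float:
    """Clamp a point prediction into the island clip range (CIs pass free)."""
    lo, hi = clip_range
    if lo > hi:
        raise ValueError("invalid clip range")
    return float(np.clip(value, lo, hi))


def gapfill_cube(
    cube: LSTCube,
    dem: DEMGrid,
    spec: SubsetSpec | None = None,
    eligibility_threshold: float = 0.5,
    collect_support: bool = False,
) -> GapfillResult:
    """Gap-fill every missing land cell-layer of a cube.

    Raises ``ValueError`` for ineligible cubes (more than
    ``eligibility_threshold`` missing).  Observed values pass through
    unchanged; predictions are clipped to the island's observed range;
    failures (support below ``n_min``) are recorded in the failure mask.
    Deterministic for fixed inputs.

    With ``collect_support=True`` the result gains a ``support`` attribute:
    a (rows, cols, layers) int array of per-prediction support (-1
    elsewhere).
    """
    spec = spec or SubsetSpec()
    dem.validate_against(cube)
    if not eligible_for_gapfill(cube, eligibility_threshold):
        raise ValueError(
            "cube ineligible for gap-filling: more than "
            f"{eligibility_threshold:.0%} of land cell-layers are missing"
        )
    clip_range = spec.clip_range or compute_clip_range(cube)

    obs = cube.copy()
    mean = cube.copy()
    shape = cube.values.shape
    lower = np.full(shape, np.nan)
    upper = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    support = np.full(shape, -1, dtype=int) if collect_support else None

    gaps = np.nonzero(~np.isfinite(cube.values) & cube.land_mask[:, :, None])
    for row, col, t in zip(*gaps):
        subset = extract_subset(cube, dem, (int(row), int(col)), int(t), spec)
        pred = qr_predict(subset, estimate_target_quantile(subset), spec)
        if pred is None:
            failed[row, col, t] = True
            continue
        clipped = clip_mean(pred.mean, clip_range)
        mean.values[row, col, t] = clipped
        # the interval must contain the reported point prediction even after
        # clipping; CIs themselves are never clipped
        lower[row, col, t] = min(pred.lower, clipped)
        upper[row, col, t] = max(pred.upper, clipped)
        if support is not None:
            support[row, col, t] = pred.support

    def _cube(values: np.ndarray) -> LSTCube:
        out = cube.copy()
        out.values = values
        return out

    result = GapfillResult(
        mean=mean,
        lower_ci=_cube(lower),
        upper_ci=_cube(upper),
        obs=obs,
        failed=failed,
        clip_range=clip_range,
    )
    if support is not None:
        result.support = support
    return result
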