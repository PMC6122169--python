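"""Technical validation machinery for the gap-filler.

Knockout scenarios (random points and 3x3 spatial clusters), error
statistics, median support-error quantile regression with Koenker-Machado
pseudo-r2, global Moran's I, and the two missingness / error-frequency
GLM diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from islefill.gapfill import SubsetSpec, gapfill_cube
from islefill.grids import IslandScene, LSTCube
from islefill.quantreg import fit_quantile, pinball_loss

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------


@dataclass
class KnockoutResult:
    """A thinned cube plus the record of what was deleted."""

    cube: LSTCube
    deleted: np.ndarray  # (k, 3) int array of (row, col, layer)
    deleted_values: np.ndarray  # (k,) the withheld truth
    achieved_fraction: float
    seed: int


def knockout_random(cube: LSTCube, fraction: float, seed: int) -> KnockoutResult:
    """Delete exactly ``round(fraction * n_observed)`` observed cells at random."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    observed = np.argwhere(np.isfinite(cube.values) & cube.land_mask[:, :, None])
    n_obs = observed.shape[0]
    k = int(round(fraction * n_obs))
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_obs, size=k, replace=False)
    deleted = observed[np.sort(pick)]
    out = cube.copy()
    vals = out.values[deleted[:, 0], deleted[:, 1], deleted[:, 2]].copy()
    out.values[deleted[:, 0], deleted[:, 1], deleted[:, 2]] = np.nan
    return KnockoutResult(
        cube=out,
        deleted=deleted,
        deleted_values=vals,
        achieved_fraction=k / n_obs if n_obs else 0.0,
        seed=seed,
    )


def knockout_clustered(cube: LSTCube, fraction: float, seed: int) -> KnockoutResult:
    """Delete observed cells in random 3x3 spatial blocks until >= ``fraction``.

    Block centres are drawn uniformly over land cell-layers; blocks are
    truncated at grid edges and overlapping deletions count once, so the
    achieved fraction can overshoot the target by at most one block
    (9/n_observed).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = cube.copy()
    finite = np.isfinite(out.values) & cube.land_mask[:, :, None]
    n_obs = int(finite.sum())
    if n_obs == 0:
        raise ValueError("fraction unreachable: cube has no observations")
    target = int(np.ceil(fraction * n_obs))
    n_rows, n_cols, n_layers = out.values.shape
    land_rc = np.argwhere(cube.land_mask)
    deleted: list[tuple[int, int, int]] = []
    n_deleted = 0
    while n_deleted < target:
        row, col = land_rc[rng.integers(len(land_rc))]
        t = int(rng.integers(n_layers))
        r0, r1 = max(0, row - 1), min(n_rows, row + 2)
        c0, c1 = max(0, col - 1), min(n_cols, col + 2)
        block = finite[r0:r1, c0:c1, t]
        if not block.any():
            continue
        rs, cs = np.nonzero(block)
        for r, c in zip(rs + r0, cs + c0):
            deleted.append((int(r), int(c), t))
        finite[r0:r1, c0:c1, t] = False
        n_deleted += len(rs)
    deleted_arr = np.array(deleted, dtype=int)
    vals = out.values[deleted_arr[:, 0], deleted_arr[:, 1], deleted_arr[:, 2]].copy()
    out.values[deleted_arr[:, 0], deleted_arr[:, 1], deleted_arr[:, 2]] = np.nan
    return KnockoutResult(
        cube=out,
        deleted=deleted_arr,
        deleted_values=vals,
        achieved_fraction=n_deleted / n_obs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# error statistics
# ---------------------------------------------------------------------------


@dataclass
class ErrorStats:
    """Scenario-level accuracy summary (observed minus predicted)."""

    rmse: float
    mean_error: float
    error_range: float
    error_sd: float
    n_failed: int
    n: int


def error_stats(
    predicted: np.ndarray, truth: np.ndarray, n_failed: int = 0
) -> ErrorStats:
    """Error statistics over successfully predicted deletions.

    ``error = observed - predicted``; negative mean error means the
    predictions ran warm.  ``error_sd`` is the n-1 sample SD.
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ok = np.isfinite(predicted) & np.isfinite(truth)
    err = truth[ok] - predicted[ok]
    if err.size == 0:
        raise ValueError("no successfully predicted deletions to score")
    return ErrorStats(
        rmse=float(np.sqrt(np.mean(err**2))),
        mean_error=float(err.mean()),
        error_range=float(err.max() - err.min()),
        error_sd=float(err.std(ddof=1)) if err.size > 1 else 0.0,
        n_failed=int(n_failed),
        n=int(err.size),
    )


# ---------------------------------------------------------------------------
# support-error quantile regression
# ---------------------------------------------------------------------------


@dataclass
class SupportErrorFit:
    """Median regression of absolute error on support."""

    intercept: float
    slope: float
    slope_se: float
    t: float
    p: float
    pseudo_r2: float
    n: int
    mean_support: float
    min_support: int


def support_error_qr(
    abs_errors: np.ndarray,
    supports: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> SupportErrorFit:
    """Median (tau=0.5) quantile regression of |error| on support.

    The goodness of fit is the Koenker-Machado R1: one minus the ratio of
    tau-weighted absolute-residual sums of the full vs the intercept-only
    (sample median) fit.  Slope inference is by seeded case-resampling
    bootstrap; the p-value uses a t reference distribution with n-2 df.
    """
    abs_errors = np.asarray(abs_errors, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if abs_errors.shape != supports.shape or abs_errors.ndim != 1:
        raise ValueError("abs_errors and supports must be 1-d and aligned")
    n = abs_errors.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(supports) < 1e-12:
        raise ValueError("supports are constant; slope undefined")
    X = np.column_stack([np.ones(n), supports])
    beta = fit_quantile(X, abs_errors, 0.5)
    v_full = pinball_loss(abs_errors, X @ beta, 0.5)
    v_null = pinball_loss(abs_errors, np.full(n, np.median(abs_errors)), 0.5)
    pseudo_r2 = 0.0 if v_null <= 0 else float(np.clip(1.0 - v_full / v_null, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(supports[idx]) < 1e-12:
            slopes[b] = beta[1]
            continue
        slopes[b] = fit_quantile(X[idx], abs_errors[idx], 0.5)[1]
    se = float(slopes.std(ddof=1))
    t_stat = beta[1] / se if se > 0 else np.inf * np.sign(beta[1] or 1)
    p = float(2 * stats.t.sf(abs(t_stat), df=n - 2)) if np.isfinite(t_stat) else 0.0
    return SupportErrorFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_se=se,
        t=float(t_stat),
        p=p,
        pseudo_r2=pseudo_r2,
        n=n,
        mean_support=float(supports.mean()),
        min_support=int(supports.min()),
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z: float
    p: float
    n: int


def _queen_neighbours(rows: np.ndarray, cols: np.ndarray, rook: bool = False):
    """Sparse neighbour pairs (i, j) among listed grid cells."""
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    if rook:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    pairs_i, pairs_j = [], []
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                pairs_i.append(i)
                pairs_j.append(j)
    return np.array(pairs_i), np.array(pairs_j)


def morans_i(
    cell_values: np.ndarray,
    neighbourhood: str = "queen",
    row_standardize: bool = True,
) -> MoranResult:
    """Global Moran's I of a per-cell statistic on a grid.

    ``cell_values`` is a 2-d array; non-finite cells (sea) are excluded.
    Weights are queen (or rook) contiguity, optionally row-standardized;
    expectation, variance and the two-sided p-value follow the normality
    assumption.
    """
    grid = np.asarray(cell_values, dtype=float)
    if grid.ndim != 2:
        raise ValueError("cell_values must be a 2-d grid")
    rows, cols = np.nonzero(np.isfinite(grid))
    n = rows.size
    if n < 9:
        raise ValueError("need at least 9 cells with values")
    x = grid[rows, cols]
    if np.ptp(x) < 1e-15:
        raise ValueError("constant field: Moran's I undefined")
    pi, pj = _queen_neighbours(rows, cols, rook=(neighbourhood == "rook"))
    w = np.ones(pi.size)
    if row_standardize:
        counts = np.bincount(pi, minlength=n).astype(float)
        w = 1.0 / counts[pi]
    W = w.sum()
    z = x - x.mean()
    num = np.sum(w * z[pi] * z[pj])
    I = (n / W) * num / np.sum(z**2)

    expected = -1.0 / (n - 1)
    # normality-assumption variance (Cliff & Ord)
    w_sym = {}
    for a, b, wt in zip(pi, pj, w):
        w_sym[(a, b)] = w_sym.get((a, b), 0.0) + wt
    s1 = 0.0
    seen = set()
    for (a, b), wab in w_sym.items():
        if (a, b) in seen:
            continue
        seen.add((a, b))
        seen.add((b, a))
        wba = w_sym.get((b, a), 0.0)
        s1 += 0.5 * (wab + wba) ** 2
    w_out = np.zeros(n)
    w_in = np.zeros(n)
    np.add.at(w_out, pi, w)
    np.add.at(w_in, pj, w)
    s2 = float(np.sum((w_out + w_in) ** 2))
    var = (n**2 * s1 - n * s2 + 3 * W**2) / (W**2 * (n**2 - 1)) - expected**2
    z_score = (I - expected) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z_score)))
    return MoranResult(I=float(I), expected_I=expected, variance=float(var),
                       z=float(z_score), p=p, n=n)


# ---------------------------------------------------------------------------
# GLM diagnostics
# ---------------------------------------------------------------------------


def missingness_glm(table: pd.DataFrame):
    """Binomial logit GLM of missingness on photoperiod, season and elevation.

    ``table`` must have columns ``is_missing`` (0/1), ``photoperiod``,
    ``season`` (categorical) and ``elevation``.  Raises on single-class
    outcomes and flags complete separation instead of returning silently.
    """
    y = table["is_missing"]
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; GLM not identified")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = smf.glm(
                "is_missing ~ C(photoperiod) + C(season) + elevation",
                data=table,
                family=sm.families.Binomial(),
            )
            result = model.fit(tol=1e-8, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise ValueError("complete separation detected in missingness GLM") from exc
    if np.abs(result.params).max() > 50:
        raise ValueError("complete separation suspected: diverging coefficients")
    return result


def error_freq_glm(table: pd.DataFrame):
    """Negative-binomial (log link, ML dispersion) GLM of error counts.

    ``table`` must have columns ``count`` (frequency of gap-fill errors
    above the caller's threshold per cell), ``photoperiod`` and
    ``elevation``.
    """
    if (table["count"] == 0).all():
        raise ValueError("all counts are zero; NB GLM not identified")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.negativebinomial(
            "count ~ C(photoperiod) + elevation", data=table
        )
        result = model.fit(disp=False, maxiter=200)
    return result


# ---------------------------------------------------------------------------
# the suite
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Scenario-level error statistics and support-error fits."""

    island: str
    mode: str
    seed: int
    rows: list[dict] = field(default_factory=list)
    support_fits: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def support_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.support_fits)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "error_stats.csv", index=False)
        if self.support_fits:
            self.support_dataframe().to_csv(out / "support_error.csv", index=False)
        (out / "report.json").write_text(json.dumps(asdict(self), indent=2))


def run_validation_suite(
    scene: IslandScene,
    mode: str = "random",
    fractions=DEFAULT_FRACTIONS,
    spec: SubsetSpec | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Run knockout -> gap-fill -> scoring for each photoperiod and fraction.

    In clustered mode, per-deletion support is collected and a median
    support-error quantile regression is fitted per scenario.
    """
    if mode not in ("random", "clustered"):
        raise ValueError("mode must be 'random' or 'clustered'")
    spec = spec or SubsetSpec()
    report = ValidationReport(island=scene.name, mode=mode, seed=seed)
    for photoperiod in ("Day", "Night"):
        cube = scene.cube(photoperiod)
        missing_frac = 1.0 - np.isfinite(cube.values[cube.land_mask]).mean()
        if missing_frac > 0.10:
            warnings.warn(
                f"{scene.name} {photoperiod}: {missing_frac:.1%} missing exceeds "
                "the 10% guideline for knockout validation",
                stacklevel=2,
            )
        for i, fraction in enumerate(fractions):
            run_seed = seed * 1000 + i * 10 + (0 if photoperiod == "Day" else 1)
            knock = (
                knockout_random(cube, fraction, run_seed)
                if mode == "random"
                else knockout_clustered(cube, fraction, run_seed)
            )
            result = gapfill_cube(knock.cube, scene.dem, spec,
                                  collect_support=(mode == "clustered"))
            idx = knock.deleted
            pred = result.mean.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            n_failed = int(result.failed[idx[:, 0], idx[:, 1], idx[:, 2]].sum())
            es = error_stats(pred, knock.deleted_values, n_failed=n_failed)
            report.rows.append(
                {
                    "island": scene.name,
                    "photoperiod": photoperiod,
                    "fraction": fraction,
                    "achieved_fraction": knock.achieved_fraction,
                    **asdict(es),
                }
            )
            if mode == "clustered":
                supports = result.support[idx[:, 0], idx[:, 1], idx[:, 2]]
                ok = np.isfinite(pred) & (supports >= 0)
                abs_err = np.abs(knock.deleted_values[ok] - pred[ok])
                fit = support_error_qr(abs_err, supports[ok], seed=run_seed)
                report.support_fits.append(
                    {
                        "island": scene.name,
                        "photoperiod": photoperiod,
                        "fraction": fraction,
                        **asdict(fit),
                    }
                )
    return report


def climatology_impute(cube: LSTCube, deleted: np.ndarray) -> np.ndarray:
    """Baseline imputer: per-cell climatological month mean.

    Predicts each deleted (row, col, layer) as the mean of the cell's
    observed values in the same calendar month (falling back to the cell's
    overall mean, then the layer's spatial mean).  Used as the reference
    the gap-filler must beat.
    """
    months = np.array([m for _, m in cube.layers])
    pred = np.empty(deleted.shape[0])
    for k, (row, col, t) in enumerate(deleted):
        series = cube.values[row, col, :]
        same_month = np.isfinite(series) & (months == months[t])
        if same_month.any():
            pred[k] = series[same_month].mean()
        elif np.isfinite(series).any():
            pred[k] = series[np.isfinite(series)].mean()
        else:
            layer = cube.values[:, :, t]
            pred[k] = np.nanmean(layer)
    return pred
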