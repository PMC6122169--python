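"""Knockouts, error statistics, support-error regression, Moran's I, GLMs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from islefill.gapfill import SubsetSpec
from islefill.quantreg import fit_quantile_brute, pinball_loss
from islefill.validation import (
    error_freq_glm,
    error_stats,
    knockout_clustered,
    knockout_random,
    missingness_glm,
    morans_i,
    run_validation_suite,
    support_error_qr,
)
from tests.conftest import full_land_cube


class TestKnockoutRandom:
    def test_exact_count(self):
        cube, _ = full_land_cube(n_rows=10, n_cols=10, n_years=1)
        n_obs = cube.n_observed()
        assert n_obs == 1200
        res = knockout_random(cube, 0.10, seed=0)
        assert len(res.deleted) == round(0.10 * n_obs)
        assert (~np.isfinite(res.cube.values)).sum() == len(res.deleted)

    def test_rounding_rule(self):
        cube, _ = full_land_cube(n_rows=10, n_cols=10, n_years=1)
        cube.values[:, :, 2:] = np.nan  # leave 200 observed
        cube.values[:, :5, :2] = np.nan  # leave 100 observed
        assert cube.n_observed() == 100
        res = knockout_random(cube, 0.10, seed=1)
        assert len(res.deleted) == 10

    def test_deterministic(self):
        cube, _ = full_land_cube(n_rows=8, n_cols=8, n_years=1)
        a = knockout_random(cube, 0.2, seed=42)
        b = knockout_random(cube, 0.2, seed=42)
        np.testing.assert_array_equal(a.deleted, b.deleted)

    def test_only_observed_cells_deleted(self):
        rng = np.random.default_rng(2)
        cube, _ = full_land_cube(n_rows=8, n_cols=8, n_years=1)
        pre_missing = rng.random(cube.values.shape) < 0.3
        cube.values[pre_missing] = np.nan
        res = knockout_random(cube, 0.25, seed=3)
        for r, c, t in res.deleted:
            assert not pre_missing[r, c, t]
        assert np.isfinite(res.deleted_values).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_fraction_guard(self, bad):
        cube, _ = full_land_cube()
        with pytest.raises(ValueError):
            knockout_random(cube, bad, seed=0)


class TestKnockoutClustered:
    def test_single_interior_block(self):
        cube, _ = full_land_cube(n_rows=10, n_cols=10, n_years=1)
        cube.values = cube.values[:, :, :1]
        cube.layers = cube.layers[:1]
        # find a seed whose first centre is interior -> exactly 9 deletions
        for seed in range(100):
            res = knockout_clustered(cube, 0.05, seed=seed)
            if len(res.deleted) == 9:
                rows, cols = res.deleted[:, 0], res.deleted[:, 1]
                assert rows.max() - rows.min() == 2
                assert cols.max() - cols.min() == 2
                break
        else:
            pytest.fail("no interior-centre seed found in 100 tries")

    def test_corner_block_truncates_to_4(self):
        cube, _ = full_land_cube(n_rows=10, n_cols=10, n_years=1)
        cube.values = cube.values[:, :, :1]
        cube.layers = cube.layers[:1]
        for seed in range(500):
            res = knockout_clustered(cube, 0.03, seed=seed)
            rows, cols = res.deleted[:, 0], res.deleted[:, 1]
            corner = (
                len(res.deleted) == 4
                and {0, 9} & set(rows.tolist())
                and {0, 9} & set(cols.tolist())
            )
            if corner:
                break
        else:
            pytest.fail("no corner-centre seed found")

    def test_overshoot_bound(self):
        cube, _ = full_land_cube(n_rows=14, n_cols=14, n_years=3)
        n = cube.n_observed()
        res = knockout_clustered(cube, 0.10, seed=7)
        assert 0.10 <= res.achieved_fraction <= 0.10 + 9 / n + 1e-12

    def test_deterministic(self):
        cube, _ = full_land_cube(n_rows=10, n_cols=10, n_years=2)
        a = knockout_clustered(cube, 0.15, seed=9)
        b = knockout_clustered(cube, 0.15, seed=9)
        np.testing.assert_array_equal(a.deleted, b.deleted)

    def test_unreachable_fraction(self):
        cube, _ = full_land_cube(n_rows=8, n_cols=8, n_years=1)
        cube.values[:] = np.nan
        with pytest.raises(ValueError, match="unreachable"):
            knockout_clustered(cube, 0.9, seed=0)


class TestErrorStats:
    def test_perfect_predictions(self):
        truth = np.arange(10.0)
        es = error_stats(truth, truth)
        assert (es.rmse, es.mean_error, es.error_range, es.error_sd,
                es.n_failed) == (0, 0, 0, 0, 0)

    def test_plus_minus_one(self):
        es = error_stats(np.array([0.0, 0.0]), np.array([1.0, -1.0]))
        assert es.rmse == pytest.approx(1.0)
        assert es.mean_error == pytest.approx(0.0)
        assert es.error_range == pytest.approx(2.0)
        assert es.error_sd == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(size=200)
        pred = truth + rng.normal(size=200)
        es = error_stats(pred, truth)
        err = truth - pred
        assert es.rmse == pytest.approx(np.sqrt((err**2).mean()))
        assert es.mean_error == pytest.approx(err.mean())
        assert es.error_range == pytest.approx(err.max() - err.min())
        assert es.error_sd == pytest.approx(err.std(ddof=1))

    def test_rmse_identity(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(size=500)
        pred = truth + rng.normal(0.3, 1.1, size=500)
        es = error_stats(pred, truth)
        n = es.n
        assert es.rmse**2 == pytest.approx(
            es.mean_error**2 + es.error_sd**2 * (n - 1) / n
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_stats(np.array([np.nan]), np.array([1.0]))


class TestSupportErrorQr:
    def test_perfect_linear_fit(self):
        supports = np.arange(10, 60, dtype=float)
        errors = 0.5 + 0.01 * supports
        fit = support_error_qr(errors, supports, seed=0)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.01, abs=1e-9)
        assert fit.mean_support == pytest.approx(supports.mean())
        assert fit.min_support == 10

    def test_null_rejection_rate(self):
        n = 2000
        rejections = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            supports = rng.integers(50, 1500, size=n).astype(float)
            errors = np.abs(rng.normal(size=n))
            fit = support_error_qr(errors, supports, n_boot=100, seed=seed)
            if fit.p <= 0.05:
                rejections += 1
        assert reps - rejections >= int(0.9 * reps)

    def test_small_dataset_matches_brute_force(self):
        rng = np.random.default_rng(6)
        supports = rng.integers(1, 30, size=12).astype(float)
        errors = np.abs(rng.normal(size=12))
        fit = support_error_qr(errors, supports, seed=0)
        X = np.column_stack([np.ones(12), supports])
        beta = fit_quantile_brute(X, errors, 0.5)
        got = pinball_loss(errors, X @ np.array([fit.intercept, fit.slope]), 0.5)
        want = pinball_loss(errors, X @ beta, 0.5)
        assert abs(got - want) < 1e-8

    def test_constant_supports_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            support_error_qr(np.abs(np.random.default_rng(0).normal(size=20)),
                             np.full(20, 7.0))


def _brute_force_moran(grid, rook=False):
    """Independent double-sum oracle with row-standardized weights."""
    rows, cols = np.nonzero(np.isfinite(grid))
    n = rows.size
    x = grid[rows, cols]
    z = x - x.mean()
    cells = list(zip(rows.tolist(), cols.tolist()))
    idx = {rc: i for i, rc in enumerate(cells)}
    num = 0.0
    W = 0.0
    for i, (r, c) in enumerate(cells):
        neigh = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                if rook and dr != 0 and dc != 0:
                    continue
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    neigh.append(j)
        if not neigh:
            continue
        w = 1.0 / len(neigh)
        for j in neigh:
            num += w * z[i] * z[j]
            W += w
    return (n / W) * num / np.sum(z**2)


class TestMoransI:
    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(7)
        grid = rng.normal(size=(10, 10))
        res = morans_i(grid)
        assert res.n == 100
        assert res.expected_I == pytest.approx(-1 / 99)

    def test_checkerboard_negative_and_matches_oracle(self):
        grid = np.indices((5, 5)).sum(axis=0) % 2
        res = morans_i(grid.astype(float))
        assert res.I < res.expected_I
        assert abs(res.I - _brute_force_moran(grid.astype(float))) < 1e-12

    def test_random_grid_matches_oracle(self):
        rng = np.random.default_rng(8)
        grid = rng.normal(size=(8, 8))
        grid[0, :3] = np.nan  # ragged support
        res = morans_i(grid)
        assert abs(res.I - _brute_force_moran(grid)) < 1e-12

    def test_rook_matches_oracle(self):
        rng = np.random.default_rng(9)
        grid = rng.normal(size=(7, 7))
        res = morans_i(grid, neighbourhood="rook")
        assert abs(res.I - _brute_force_moran(grid, rook=True)) < 1e-12

    def test_smooth_gradient_positive_significant(self):
        grid = np.add.outer(np.arange(12.0), np.arange(12.0))
        res = morans_i(grid)
        assert res.I > 0
        assert res.p < 0.05

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones((5, 5)))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.arange(4.0).reshape(2, 2))


def _simulate_missingness_table(n, b_elev, seed):
    rng = np.random.default_rng(seed)
    elevation = rng.uniform(0, 1200, size=n)
    photoperiod = rng.choice(["Day", "Night"], size=n)
    season = rng.choice(["summer", "autumn", "winter", "spring"], size=n)
    logit = (
        -1.5
        + b_elev * elevation
        + 0.5 * (photoperiod == "Day")
        + 0.7 * (season == "spring")
    )
    return pd.DataFrame(
        {
            "is_missing": (rng.random(n) < expit(logit)).astype(int),
            "photoperiod": photoperiod,
            "season": season,
            "elevation": elevation,
        }
    )


class TestMissingnessGlm:
    def test_recovers_elevation_coefficient(self):
        table = _simulate_missingness_table(50_000, b_elev=0.002, seed=0)
        fit = missingness_glm(table)
        est = fit.params["elevation"]
        se = fit.bse["elevation"]
        assert abs(est - 0.002) < 3 * se

    def test_type_one_error_calibration(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            table = _simulate_missingness_table(20_000, b_elev=0.0, seed=seed)
            fit = missingness_glm(table)
            z = fit.params["elevation"] / fit.bse["elevation"]
            if abs(z) < 1.96:
                hits += 1
        assert hits >= 16  # ~95% coverage

    def test_single_class_rejected(self):
        table = _simulate_missingness_table(100, b_elev=0.0, seed=1)
        table["is_missing"] = 0
        with pytest.raises(ValueError, match="single class"):
            missingness_glm(table)

    def test_separation_flagged(self):
        n = 200
        rng = np.random.default_rng(2)
        elevation = np.concatenate([rng.uniform(0, 100, n), rng.uniform(900, 1000, n)])
        table = pd.DataFrame(
            {
                "is_missing": np.r_[np.zeros(n, int), np.ones(n, int)],
                "photoperiod": ["Day"] * (2 * n),
                "season": ["spring"] * (2 * n),
                "elevation": elevation,
            }
        )
        with pytest.raises(ValueError, match="separation"):
            missingness_glm(table)


class TestErrorFreqGlm:
    @staticmethod
    def _simulate(n, b_elev, seed, size=2.0):
        rng = np.random.default_rng(seed)
        elevation = rng.uniform(0, 1000, size=n)
        photoperiod = rng.choice(["Day", "Night"], size=n)
        mu = np.exp(0.5 + b_elev * elevation + 0.3 * (photoperiod == "Day"))
        counts = rng.negative_binomial(size, size / (size + mu))
        return pd.DataFrame(
            {"count": counts, "photoperiod": photoperiod, "elevation": elevation}
        )

    def test_recovers_elevation_coefficient(self):
        table = self._simulate(20_000, b_elev=0.001, seed=0)
        fit = error_freq_glm(table)
        est = fit.params["elevation"]
        se = fit.bse["elevation"]
        assert abs(est - 0.001) < 3 * se

    def test_zero_effect_ci_coverage(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            table = self._simulate(5_000, b_elev=0.0, seed=100 + seed)
            fit = error_freq_glm(table)
            z = fit.params["elevation"] / fit.bse["elevation"]
            if abs(z) < 1.96:
                hits += 1
        assert hits >= 8

    def test_all_zero_counts_rejected(self):
        table = self._simulate(100, b_elev=0.0, seed=1)
        table["count"] = 0
        with pytest.raises(ValueError, match="zero"):
            error_freq_glm(table)


class TestValidationSuite:
    def test_single_fraction_report_shape(self, truth_scene):
        report = run_validation_suite(
            truth_scene, mode="random", fractions=(0.10,),
            spec=SubsetSpec(spatial_radius=2), seed=1,
        )
        df = report.to_dataframe()
        assert len(df) == 2  # one row per photoperiod
        assert set(df["photoperiod"]) == {"Day", "Night"}
        assert (df["n_failed"] == 0).all()

    def test_noise_free_scene_exact(self, noise_free_scene):
        report = run_validation_suite(
            noise_free_scene, mode="random", fractions=(0.05, 0.50),
            spec=SubsetSpec(spatial_radius=2), seed=2,
        )
        assert (report.to_dataframe()["rmse"] < 1e-6).all()

    def test_clustered_mode_support_fits(self, truth_scene):
        report = run_validation_suite(
            truth_scene, mode="clustered", fractions=(0.20,),
            spec=SubsetSpec(spatial_radius=2), seed=3,
        )
        sdf = report.support_dataframe()
        assert len(sdf) == 2
        assert (sdf["min_support"] >= 0).all()
        assert (sdf["pseudo_r2"] <= 1.0).all()

    def test_report_round_trip(self, truth_scene, tmp_path):
        report = run_validation_suite(
            truth_scene, mode="random", fractions=(0.10,),
            spec=SubsetSpec(spatial_radius=2), seed=4,
        )
        report.write(tmp_path)
        assert (tmp_path / "error_stats.csv").exists()
        assert (tmp_path / "report.json").exists()

    def test_warns_on_gappy_scene(self, gappy_scene):
        with pytest.warns(UserWarning, match="10%"):
            run_validation_suite(
                gappy_scene, mode="random", fractions=(0.05,),
                spec=SubsetSpec(spatial_radius=2), seed=5,
            )
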