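"""Brownian bridge moments, variance estimation, and UD rasterization."""

import numpy as np
import pytest

from conftest import make_brownian_track, make_two_regime_track
from flyway.dbbmm import (BridgeParams, VarianceProfile, bridge_moments,
                          compute_ud, dynamic_variance, fit_sigma,
                          grid_for_track, locate_change_point,
                          loo_neg_log_likelihood)
from flyway.geo_io import Grid, Track


class TestBridgeMoments:
    def test_endpoint_limits(self):
        z_i, z_j = np.array([0.0, 0.0]), np.array([100.0, 50.0])
        # alpha -> 0: mean -> z_i, variance -> err_i^2
        mean, var = bridge_moments(z_i, z_j, 0.0, 3600.0, 1e-6, 0.5, 18.0, 7.0)
        np.testing.assert_allclose(mean, z_i, atol=1e-6)
        assert var == pytest.approx(18.0**2, rel=1e-6)
        # alpha = 1 exactly: mean = z_j, variance = err_j^2
        mean, var = bridge_moments(z_i, z_j, 0.0, 3600.0, 3600.0, 0.5, 18.0, 7.0)
        np.testing.assert_allclose(mean, z_j)
        assert var == pytest.approx(7.0**2)

    def test_degenerate_zero_variance_on_chord(self):
        mean, var = bridge_moments([0.0, 0.0], [100.0, 0.0], 0.0, 100.0, 25.0,
                                   0.0, 0.0, 0.0)
        np.testing.assert_allclose(mean, [25.0, 0.0])
        assert var == 0.0

    def test_direct_substitution(self):
        """T=3600 s, alpha=0.5, sigma=0.5, err=18 m both ends:
        variance = 3600*0.25*0.5 + 0.25*324 + 0.25*324 = 612 m^2."""
        _, var = bridge_moments([0.0, 0.0], [0.0, 0.0], 0.0, 3600.0, 1800.0,
                                0.5, 18.0, 18.0)
        assert var == pytest.approx(612.0)

    def test_time_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="t must lie"):
            bridge_moments([0, 0], [1, 1], 0.0, 100.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="t must lie"):
            bridge_moments([0, 0], [1, 1], 0.0, 100.0, 101.0, 1.0)


class TestSigmaEstimation:
    def test_three_fix_closed_form(self, three_fix_track):
        """Out-and-back 60 m in 3600 s with no GPS error: the single
        left-out observation gives sigma_hat = 60^2/1800 = 2.0 m^2/s."""
        assert fit_sigma(three_fix_track) == pytest.approx(2.0, rel=0.01)

    def test_closed_form_matches_dense_grid_search(self, three_fix_track):
        """Independent oracle: brute-force NLL minimization on a very fine
        grid agrees with the closed form and with fit_sigma."""
        grid = np.linspace(0.5, 5.0, 20001)
        nll = [loo_neg_log_likelihood(three_fix_track, s) for s in grid]
        brute = grid[int(np.argmin(nll))]
        assert brute == pytest.approx(2.0, rel=1e-3)
        assert fit_sigma(three_fix_track) == pytest.approx(brute, rel=0.01)

    def test_nll_monotone_beyond_optimum(self, three_fix_track):
        vals = [loo_neg_log_likelihood(three_fix_track, s)
                for s in (2.0, 4.0, 16.0, 256.0, 4096.0)]
        assert np.all(np.diff(vals) > 0)

    def test_scaling_coordinates_scales_sigma(self, three_fix_track):
        tr = three_fix_track
        scaled = Track(tr.individual_id, tr.t, 3.0 * tr.x, 3.0 * tr.y, 0.0)
        ratio = fit_sigma(scaled) / fit_sigma(tr)
        assert ratio == pytest.approx(9.0, rel=0.02)

    def test_stationary_noisy_fixes_near_zero(self):
        """A perched bird (stationary truth, 18 m GPS noise) should yield
        essentially zero motion variance."""
        sigmas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 31
            tr = Track("perch", np.arange(n) * 3600.0,
                       rng.normal(0, 18.0, n), rng.normal(0, 18.0, n), 18.0)
            sigmas.append(fit_sigma(tr))
        assert np.median(sigmas) <= 1e-3

    def test_identical_positions_zero_error_warns(self):
        tr = Track("still", np.arange(5) * 3600.0, np.zeros(5), np.zeros(5), 0.0)
        with pytest.warns(UserWarning, match="identical"):
            assert fit_sigma(tr) == 0.0

    def test_pure_brownian_recovery(self):
        """argmin within 15% of truth (median over 20 seeds), n=200, err=0."""
        est = [fit_sigma(make_brownian_track(seed)) for seed in range(20)]
        assert abs(np.median(est) - 0.5) / 0.5 < 0.15


class TestDynamicVariance:
    def test_profile_shape_and_counts(self, brownian_track):
        prof = dynamic_variance(brownian_track)
        assert len(prof.sigma_m2) == len(brownian_track) - 1
        assert prof.n_windows == len(brownian_track) - 17 + 1
        assert np.all(prof.sigma_m2 >= 0)
        # central intervals are informed by sliding windows
        assert prof.counts[20:-20].min() >= 1

    def test_constant_sigma_few_breakpoints(self):
        """On constant-variance tracks the single-variance model should win
        in most windows and the profile should track the truth."""
        fracs, med_err = [], []
        for seed in range(8):
            prof = dynamic_variance(make_brownian_track(seed))
            fracs.append(prof.n_breakpoint_windows / prof.n_windows)
            med_err.append(abs(np.median(prof.sigma_m2) - 0.5) / 0.5)
        assert np.mean(fracs) < 0.20
        assert max(med_err) < 0.20

    def test_two_regime_change_point_located(self):
        """Variance jump 0.2 -> 5 m^2/s at fix 150 is found within 3 fixes."""
        prof = dynamic_variance(make_two_regime_track(seed=3))
        assert abs(locate_change_point(prof) - 149) <= 3

    def test_static_reduction_same_code_path(self):
        """Breakpoints disabled + window covering the whole track reduces to
        the constant-variance Brownian bridge model, bitwise."""
        tr = make_brownian_track(seed=1, n=25)
        params = BridgeParams(window=25, margin=11, allow_breakpoints=False)
        prof = dynamic_variance(tr, params)
        sig = fit_sigma(tr, params)
        assert np.all(prof.sigma_m2 == sig)
        assert prof.n_breakpoint_windows == 0

    def test_short_track_rejected(self):
        tr = make_brownian_track(seed=0, n=10)
        with pytest.raises(ValueError, match="excluded upstream"):
            dynamic_variance(tr)


def toy_track_and_grid():
    """Small 3-fix track with a hand-built grid comfortably containing the
    3-SD bridge envelope (cell size 50 m to resolve the bridges)."""
    tr = Track("toy", [0.0, 1800.0, 3600.0], [0.0, 200.0, 100.0],
               [0.0, 100.0, 300.0], 18.0)
    prof = VarianceProfile(np.array([1.0, 3.0]), np.array([1, 1]))
    grid = Grid(-250.0, -250.0, 50.0, 14, 17)
    return tr, prof, grid


def ud_oracle(track, profile, grid, substeps=1000, subsample=5):
    """Independent fine-discretization UD: dense time steps and per-cell
    integration by subsampling each cell on a subsample x subsample lattice."""
    s = grid.cell_size / subsample
    xs = grid.x0 + (np.arange(grid.n_cols * subsample) + 0.5) * s
    ys = grid.y0 + (np.arange(grid.n_rows * subsample) + 0.5) * s
    acc = np.zeros((len(ys), len(xs)))
    t, x, y, err = track.t, track.x, track.y, track.err_sd
    for i in range(len(track) - 1):
        dt = t[i + 1] - t[i]
        for k in range(substeps):
            alpha = (k + 0.5) / substeps
            mx = (1 - alpha) * x[i] + alpha * x[i + 1]
            my = (1 - alpha) * y[i] + alpha * y[i + 1]
            var = dt * alpha * (1 - alpha) * profile.sigma_m2[i] \
                + (1 - alpha) ** 2 * err[i] ** 2 + alpha ** 2 * err[i + 1] ** 2
            gx = np.exp(-((xs - mx) ** 2) / (2 * var))
            gy = np.exp(-((ys - my) ** 2) / (2 * var))
            acc += (dt / substeps) / (2 * np.pi * var) * np.outer(gy, gx)
    # block-average subcells into cells, convert density to cell mass
    cells = acc.reshape(grid.n_rows, subsample, grid.n_cols, subsample) \
        .mean(axis=(1, 3)) * grid.cell_size ** 2
    return cells / cells.sum()


class TestComputeUD:
    def test_sums_to_one(self, brownian_track):
        prof = dynamic_variance(brownian_track)
        grid = grid_for_track(brownian_track, prof)
        ud = compute_ud(brownian_track, prof, grid)
        assert ud.sum() == pytest.approx(1.0, abs=1e-6)
        assert ud.n_fixes == len(brownian_track)

    def test_matches_fine_discretization_oracle(self):
        """Default substeps=10 agrees with a 1000-substep, 5x5
        cell-integrated oracle to within 2% of the oracle's max cell."""
        tr, prof, grid = toy_track_and_grid()
        coarse = compute_ud(tr, prof, grid, BridgeParams(substeps=10)).values
        fine = ud_oracle(tr, prof, grid)
        assert np.abs(coarse - fine).max() <= 0.02 * fine.max()

    def test_mirror_symmetry_exact(self):
        tr, prof, _ = toy_track_and_grid()
        grid = Grid(-400.0, -400.0, 50.0, 16, 16)   # symmetric about y=0
        mirrored = Track(tr.individual_id, tr.t, tr.x, -tr.y, tr.err_sd)
        ud = compute_ud(tr, prof, grid, BridgeParams(substeps=10))
        ud_m = compute_ud(mirrored, prof, grid, BridgeParams(substeps=10))
        np.testing.assert_array_equal(ud_m.values, ud.values[::-1])

    def test_translation_equivariance(self):
        tr, prof, grid = toy_track_and_grid()
        dx, dy = 12_000.0, -7_000.0
        shifted = Track(tr.individual_id, tr.t, tr.x + dx, tr.y + dy, tr.err_sd)
        sgrid = Grid(grid.x0 + dx, grid.y0 + dy, grid.cell_size,
                     grid.n_cols, grid.n_rows)
        ud = compute_ud(tr, prof, grid)
        ud_s = compute_ud(shifted, prof, sgrid)
        np.testing.assert_allclose(ud_s.values, ud.values, rtol=1e-9, atol=1e-18)

    def test_small_grid_rejected(self):
        tr, prof, _ = toy_track_and_grid()
        tight = Grid(0.0, 0.0, 50.0, 3, 3)
        with pytest.raises(ValueError, match="3-SD envelope"):
            compute_ud(tr, prof, tight, BridgeParams(substeps=10))

    def test_profile_length_checked(self):
        tr, _, grid = toy_track_and_grid()
        bad = VarianceProfile(np.array([1.0]), np.array([1]))
        with pytest.raises(ValueError, match="n_fixes - 1"):
            compute_ud(tr, bad, grid)


class TestGridForTrack:
    def test_buffer_at_least_30km(self, brownian_track):
        prof = dynamic_variance(brownian_track)
        grid = grid_for_track(brownian_track, prof)
        assert brownian_track.x.min() - grid.x0 >= 30_000.0
        assert grid.x_max - brownian_track.x.max() >= 30_000.0
        assert grid.cell_size == 1000.0


class TestBridgeParams:
    @pytest.mark.parametrize("kwargs", [
        {"window": 16}, {"margin": 2}, {"window": 15, "margin": 7},
        {"substeps": 0}])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BridgeParams(**kwargs)
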