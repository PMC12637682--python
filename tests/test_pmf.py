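import numpy as np
import pytest

from ionflux import reference
from ionflux.pmf import (AbfWindow, ConvergenceHistory, Pmf2D,
                         abf_accumulate, convergence_check,
                         integrate_gradient, run_abf, sampling_entropy,
                         sampling_heterogeneity, stitch_windows, string_mfep)


def quad_grid(shape=(20, 20), origin=(-1.0, -1.0), counts=10):
    """Grid loaded with the exact force field of F = x² + y²."""
    g = Pmf2D(origin=origin, widths=(0.1, 0.1), shape=shape)
    xs, ys = g.centers()
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    g.counts[:] = counts
    g.force_sum[..., 0] = -2 * xx * counts
    g.force_sum[..., 1] = -2 * yy * counts
    return g, xx ** 2 + yy ** 2


class TestAccumulator:
    def test_constant_force_running_mean(self):
        g = Pmf2D(origin=(0, 0), widths=(1.0, 1.0), shape=(2, 2))
        pos = np.tile([0.5, 0.5], (7, 1))
        f = np.tile([1.25, -0.5], (7, 1))
        abf_accumulate(pos, f, g)
        assert g.counts[0, 0] == 7
        assert g.mean_force()[0, 0] == pytest.approx([1.25, -0.5])

    def test_ramp_definition(self):
        g = Pmf2D(origin=(0, 0), widths=(1.0, 1.0), shape=(1, 1), n0=250)
        g.counts[0, 0] = 125
        assert g.ramp()[0, 0] == pytest.approx(0.5)
        g.counts[0, 0] = 600
        assert g.ramp()[0, 0] == 1.0

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 2, (500, 2))
        f = rng.normal(size=(500, 2))
        g1 = Pmf2D(origin=(0, 0), widths=(0.5, 0.5), shape=(4, 4))
        g2 = Pmf2D(origin=(0, 0), widths=(0.5, 0.5), shape=(4, 4))
        abf_accumulate(pos, f, g1)
        perm = rng.permutation(500)
        abf_accumulate(pos[perm], f[perm], g2)
        assert np.array_equal(g1.counts, g2.counts)
        assert np.allclose(g1.force_sum, g2.force_sum)

    def test_outside_grid_rejected(self):
        g = Pmf2D(origin=(0, 0), widths=(1.0, 1.0), shape=(2, 2))
        with pytest.raises(ValueError, match="outside"):
            abf_accumulate([[5.0, 0.5]], [[0.0, 0.0]], g)


class TestSamplingDiagnostics:
    def test_uniform_counts_max_entropy_zero_heterogeneity(self):
        counts = np.full((5, 4), 17)
        assert sampling_entropy(counts) == pytest.approx(np.log(20))
        assert sampling_heterogeneity(counts) == 0.0

    def test_single_bin_entropy_zero(self):
        counts = np.zeros((5, 4), dtype=int)
        counts[2, 2] = 99
        assert sampling_entropy(counts) == 0.0

    def test_entropy_below_uniform_when_skewed(self):
        counts = np.array([[1000, 1], [1, 1]])
        assert sampling_entropy(counts) < np.log(4)
        assert sampling_heterogeneity(counts) > 0


class TestIntegrateGradient:
    def test_exact_quadratic_identity(self):
        g, f_true = quad_grid()
        f = integrate_gradient(g)
        err = (f - np.nanmean(f)) - (f_true - f_true.mean())
        assert np.nanmax(np.abs(err)) < 1e-6 * np.ptp(f_true)
        assert g.residual < 1e-9

    def test_min_is_zero(self):
        g, _ = quad_grid()
        f = integrate_gradient(g)
        assert np.nanmin(f) == pytest.approx(0.0, abs=1e-12)

    def test_curl_field_flagged_by_residual(self):
        g = Pmf2D(origin=(-1, -1), widths=(0.1, 0.1), shape=(20, 20))
        xs, ys = g.centers()
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        g.counts[:] = 10
        g.force_sum[..., 0] = -yy * 10
        g.force_sum[..., 1] = xx * 10
        integrate_gradient(g)
        assert g.residual > 0.01  # no potential exists for a rotational field

    def test_noisy_gradient_vs_line_integral_oracle(self):
        rng = np.random.default_rng(5)
        g = Pmf2D(origin=(0, 0), widths=(0.1, 0.1), shape=(25, 25))
        xs, ys = g.centers()
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        f_true = np.sin(2 * xx) + 0.5 * np.cos(3 * yy) + xx * yy
        fx = -(2 * np.cos(2 * xx) + yy)
        fy = -(-1.5 * np.sin(3 * yy) + xx)
        noise = 0.05
        n_per = 200
        g.counts[:] = n_per
        g.force_sum[..., 0] = (fx + noise * rng.standard_normal(fx.shape)
                               / np.sqrt(n_per)) * n_per
        g.force_sum[..., 1] = (fy + noise * rng.standard_normal(fy.shape)
                               / np.sqrt(n_per)) * n_per
        f = integrate_gradient(g)
        oracle = reference.line_integral_surface(g.mean_force()[..., 0],
                                                 g.mean_force()[..., 1],
                                                 0.1, 0.1)
        d = (f - np.nanmean(f)) - (oracle - oracle.mean())
        # least squares and direct integration agree to the noise scale
        assert np.sqrt(np.nanmean(d ** 2)) < 5 * noise

    def test_disconnected_components_each_anchored(self):
        g = Pmf2D(origin=(0, 0), widths=(1.0, 1.0), shape=(5, 1))
        g.counts[[0, 1], 0] = 10
        g.counts[[3, 4], 0] = 10
        g.force_sum[[0, 1], 0, 0] = -10.0 * 10
        g.force_sum[[3, 4], 0, 0] = -20.0 * 10
        f = integrate_gradient(g)
        assert np.isnan(f[2, 0])
        assert f[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert f[3, 0] == pytest.approx(0.0, abs=1e-9)


class TestAbfSampler:
    def test_flat_surface_recovered_flat(self):
        grad = lambda p: np.zeros_like(p)
        win = AbfWindow(z_lo=-1.5, z_hi=1.5, disc_radius=1.0)
        pmf, hist = run_abf(grad, win, n_steps=6000, seed=2)
        well = pmf.free_energy[pmf.counts >= pmf.n0]
        assert np.ptp(well[~np.isnan(well)]) < 0.2

    def test_double_well_barrier_recovered(self):
        def grad(p):
            x, y = p[:, 0], p[:, 1]
            return np.column_stack([12 * x * (x ** 2 - 1), 2 * y])

        win = AbfWindow(z_lo=-1.6, z_hi=1.6, disc_radius=1.0)
        pmf, hist = run_abf(grad, win, n_steps=16000, seed=3)
        xs, ys = pmf.centers()
        truth = 3 * (xs[:, None] ** 2 - 1) ** 2 + ys[None, :] ** 2
        mask = (pmf.counts >= pmf.n0) & ~np.isnan(pmf.free_energy)
        d = pmf.free_energy[mask] - truth[mask]
        d -= d.mean()
        assert np.sqrt(np.mean(d ** 2)) < 0.25
        ok, t0 = convergence_check(hist, rmsd_threshold=0.1,
                                   hold_time=hist.times[-1] / 4,
                                   plateau_rel=0.05)
        assert ok

    def test_harmonic_well_mean_force(self):
        # binned mean force must match -kx at the bin centres
        def grad(p):
            return 1.5 * p

        win = AbfWindow(z_lo=-1.0, z_hi=1.0, disc_radius=1.0)
        pmf, _ = run_abf(grad, win, n_steps=6000, seed=4,
                         force_noise_sd=0.5)
        xs, ys = pmf.centers()
        mask = pmf.counts >= pmf.n0
        mf = pmf.mean_force()
        se = 0.5 / np.sqrt(pmf.counts[mask]) + 1.5 * pmf.widths[0]
        resid = np.abs(mf[mask, 0] + 1.5 * np.broadcast_to(
            xs[:, None], pmf.shape)[mask])
        assert np.mean(resid < 4 * se + 0.05) > 0.95

    def test_escape_aborts(self):
        grad = lambda p: np.full_like(p, -500.0)  # huge outward pull
        win = AbfWindow(z_lo=-1.0, z_hi=1.0, disc_radius=1.0, k=0.0)
        with pytest.raises(RuntimeError, match="escaped"):
            run_abf(grad, win, n_steps=4000, seed=5)

    def test_seed_reproducible(self):
        grad = lambda p: np.zeros_like(p)
        win = AbfWindow(z_lo=-1.0, z_hi=1.0, disc_radius=1.0)
        p1, h1 = run_abf(grad, win, n_steps=500, seed=6)
        p2, h2 = run_abf(grad, win, n_steps=500, seed=6)
        assert np.array_equal(p1.counts, p2.counts)
        assert np.allclose(p1.force_sum, p2.force_sum)


class TestConvergenceCheck:
    def test_identical_pmfs_rmsd_zero(self):
        h = ConvergenceHistory(times=[1, 2, 3, 4.0],
                               rmsd=[np.nan, 0.0, 0.0, 0.0],
                               entropy=[5.0] * 4, heterogeneity=[0.2] * 4)
        ok, t0 = convergence_check(h, hold_time=2.0)
        assert ok and t0 == 2.0

    def test_rmsd_above_threshold_never_converges(self):
        h = ConvergenceHistory(times=[1, 2, 3, 4.0],
                               rmsd=[np.nan, 0.5, 0.5, 0.5],
                               entropy=[5.0] * 4, heterogeneity=[0.2] * 4)
        ok, t0 = convergence_check(h, hold_time=2.0)
        assert not ok and t0 is None

    def test_needs_two_checkpoints(self):
        with pytest.raises(ValueError):
            convergence_check(ConvergenceHistory(times=[1.0], rmsd=[np.nan],
                                                 entropy=[1], heterogeneity=[0]))


class TestStitching:
    def test_constant_offset_join_is_seamless(self):
        g1, _ = quad_grid(shape=(10, 5), origin=(-1.0, -0.25))
        g2, _ = quad_grid(shape=(10, 5), origin=(-0.5, -0.25))
        integrate_gradient(g1)
        integrate_gradient(g2)
        g2.free_energy += 3.7  # windows disagree by a pure constant
        glob = stitch_windows([g1, g2])
        xs, ys = glob.centers()
        truth = xs[:, None] ** 2 + ys[None, :] ** 2
        d = glob.free_energy - truth
        assert np.nanstd(d) < 1e-6

    def test_three_windows_reconstruct_tilted_surface(self):
        def grad(p):
            return np.column_stack([np.full(len(p), 0.8), 2 * p[:, 1]])

        wins = [AbfWindow(z_lo=-3.0, z_hi=-0.5, disc_radius=1.0),
                AbfWindow(z_lo=-1.5, z_hi=1.5, disc_radius=1.0),
                AbfWindow(z_lo=0.5, z_hi=3.0, disc_radius=1.0)]
        pmfs, _ = run_abf(grad, wins, n_steps=6000, seed=5)
        glob = stitch_windows(pmfs)
        xs, ys = glob.centers()
        truth = 0.8 * xs[:, None] + ys[None, :] ** 2
        mask = (glob.counts >= glob.n0) & ~np.isnan(glob.free_energy)
        d = glob.free_energy[mask] - truth[mask]
        d -= d.mean()
        assert np.sqrt(np.mean(d ** 2)) < 0.1

    def test_disjoint_windows_rejected(self):
        g1, _ = quad_grid(shape=(5, 5), origin=(0.0, 0.0))
        g2, _ = quad_grid(shape=(5, 5), origin=(2.0, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            stitch_windows([g1, g2])


class TestStringMethod:
    xs = np.linspace(-2.2, 2.2, 221)
    ys = np.linspace(-1.6, 1.6, 161)

    def test_separable_valley_stays_straight(self):
        f = 2.0 * self.xs[:, None] ** 2 + 0.0 * self.ys[None, :]
        path = string_mfep((self.xs, self.ys, f), (0, -1.0), (0, 1.0),
                           n_images=50)
        assert path.converged
        assert np.abs(path.images[:, 0]).max() < 0.01
        assert np.ptp(path.energy) < 1e-3

    def test_flat_surface_straight_segment(self):
        f = np.zeros((221, 161))
        path = string_mfep((self.xs, self.ys, f), (-1.0, -1.0), (1.0, 1.0),
                           n_images=50)
        assert path.converged
        assert np.abs(path.images[:, 0] - path.images[:, 1]).max() < 0.05
        assert path.s_norm[0] == 0.0 and path.s_norm[-1] == 1.0

    def test_two_basin_saddle_matches_dijkstra(self):
        rng = np.random.default_rng(0)
        for _ in range(2):
            cx, cy = rng.uniform(-0.3, 0.3, 2)
            h = rng.uniform(2.0, 4.0)

            def f_fn(x, y):
                return (h * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / 0.5)
                        - 2 * np.exp(-((x + 1.3) ** 2 + y ** 2) / 0.4)
                        - 2 * np.exp(-((x - 1.3) ** 2 + y ** 2) / 0.4)
                        + 0.25 * y ** 2)

            f = f_fn(self.xs[:, None], self.ys[None, :])
            path = string_mfep((self.xs, self.ys, f), (-1.3, 0.0), (1.3, 0.0))
            oracle = reference.dijkstra_minimax_saddle(
                f_fn, (-1.3, 0.0), (1.3, 0.0), (-2.2, 2.2, -1.6, 1.6),
                step=0.02)
            assert path.converged
            assert path.saddle == pytest.approx(oracle, abs=0.05)
            # a continuous path can never dip below the minimax saddle
            assert path.saddle >= oracle - 1e-6

    def test_endpoints_fixed(self):
        f = np.zeros((221, 161))
        a, b = (-2.0, -1.5), (2.0, 1.5)
        path = string_mfep((self.xs, self.ys, f), a, b, n_images=30)
        assert tuple(path.images[0]) == a
        assert tuple(path.images[-1]) == b
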