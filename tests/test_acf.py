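import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxblink import (ACFCurve, SimConfig, average_acfs, compute_acf, decay_ratio,
                     dxb_pipeline, extract_trajectories, fit_averaged,
                     fit_exponential, normalize_by_background, render_frames)
from dxblink.acf import IntensityTrajectory, background_total
from dxblink.errors import EmptySelectionError, UndefinedACFError


def traj(values, dt=1.0):
    return IntensityTrajectory(pixel=(0, 0), values=np.asarray(values, float),
                               frame_interval=dt)


def brute_force_acf(x, m):
    n = len(x)
    denom = sum(v * v for v in x) / n
    return (sum(x[i] * x[i + m] for i in range(n - m)) / (n - m)) / denom


class TestExtract:
    def test_one_trajectory_per_on_ring_pixel(self, compact_geometry, compact_ring,
                                              compact_mask):
        cfg = SimConfig(n_crystallites=2, D=1e-4, peak_rate=200.0, background_rate=1.0,
                        n_frames=20, exposure=0.5, frame_interval=1.0,
                        substeps_per_frame=2, seed=21)
        stack = render_frames(cfg, compact_geometry, compact_ring)
        trajs = extract_trajectories(stack, compact_mask)
        assert len(trajs) == compact_mask.counts["on_ring"]
        assert all(len(t.values) == 20 for t in trajs)
        # row-major order and faithful read-back
        pix = [t.pixel for t in trajs]
        assert pix == sorted(pix)
        r, c = trajs[0].pixel
        assert np.array_equal(trajs[0].values, stack.counts[:, r, c].astype(float))

    def test_gap_pixels_never_emitted(self, gapped_geometry, compact_ring):
        from dxblink import build_ring_mask
        mask = build_ring_mask(gapped_geometry, compact_ring)
        assert not any(55 <= r < 65 for r, _ in map(tuple, mask.on_ring))


class TestNormalize:
    def test_flat_background_identity(self):
        t = normalize_by_background(traj([1, 2, 3, 4]), np.array([5.0, 5, 5, 5]))
        assert np.allclose(t.values, [1, 2, 3, 4])
        assert t.normalized

    def test_hand_arithmetic(self):
        out = normalize_by_background(traj([2, 2, 2, 2]), np.array([1.0, 2, 1, 2]))
        assert np.allclose(out.values, [3.0, 1.5, 3.0, 1.5])

    def test_background_scale_invariance(self):
        b = np.array([1.0, 2, 1, 2])
        a = normalize_by_background(traj([2, 2, 2, 2]), b)
        c = normalize_by_background(traj([2, 2, 2, 2]), 2 * b)
        assert np.allclose(a.values, c.values)

    def test_all_zero_background_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_background(traj([1, 1, 1, 1]), np.zeros(4))


class TestComputeACF:
    def test_constant_trajectory_is_unity(self):
        acf = compute_acf(traj([3.0] * 20), 10)
        assert np.allclose(acf.values, 1.0)

    def test_alternating_signal(self):
        acf = compute_acf(traj([1, 0, 1, 0, 1, 0, 1, 0, 1, 0]), 4)
        assert acf.values[1] == pytest.approx(0.0)
        assert acf.values[2] == pytest.approx(1.0)

    def test_lag_zero_exactly_one_and_pairs_decrease(self):
        x = np.random.default_rng(1).poisson(3, 50).astype(float)
        acf = compute_acf(traj(x), 20)
        assert acf.values[0] == 1.0
        assert np.all(np.diff(acf.n_pairs) < 0)

    def test_zero_trajectory_is_undefined(self):
        with pytest.raises(UndefinedACFError):
            compute_acf(traj(np.zeros(20)), 5)

    @given(st.lists(st.integers(0, 2), min_size=10, max_size=64))
    @settings(derandomize=True, max_examples=120)
    def test_matches_double_loop_oracle(self, counts):
        if not any(counts):
            return
        x = np.asarray(counts, float)
        acf = compute_acf(traj(x), len(x) - 1)
        for m in range(len(x)):
            assert acf.values[m] == pytest.approx(brute_force_acf(x, m), abs=1e-12)

    @pytest.mark.parametrize("mu", [0.5, 4.0, 20.0])
    def test_iid_poisson_closed_form(self, mu):
        # ACF(tau > 0) -> mu / (mu + 1) for shot-noise-only trajectories
        x = np.random.default_rng(int(mu * 10)).poisson(mu, 100_000).astype(float)
        acf = compute_acf(traj(x), 3)
        prod = x[:-1] * x[1:]
        se = prod.std() / math.sqrt(len(prod)) / np.mean(x**2)
        assert abs(acf.values[1] - mu / (mu + 1)) < 3 * se


class TestFitExponential:
    def test_noiseless_recovery(self):
        tau = np.arange(0, 102, dtype=float)
        vals = 0.4 + 0.6 * np.exp(-0.1 * tau)
        curve = ACFCurve(lags=tau, values=vals, n_pairs=1000 - np.arange(102))
        f = fit_exponential(curve, 0.10)
        assert f.valid
        for got, want in ((f.k, 0.4), (f.A, 0.6), (f.T, 0.1)):
            assert abs(got - want) / want < 1e-6

    def test_flat_curve_is_invalid(self):
        tau = np.arange(0, 60, dtype=float)
        curve = ACFCurve(lags=tau, values=np.ones(60), n_pairs=500 - np.arange(60))
        f = fit_exponential(curve, 0.10)
        assert not f.valid

    def test_window_override_selects_lags(self):
        tau = np.arange(0, 102, dtype=float)
        vals = 0.4 + 0.6 * np.exp(-0.1 * tau)
        curve = ACFCurve(lags=tau, values=vals, n_pairs=1000 - np.arange(102))
        f = fit_exponential(curve, window_override=(1.0, 30.0))
        assert f.fit_window == (1.0, 30.0)
        assert f.T == pytest.approx(0.1, rel=1e-6)

    def test_too_few_lags_rejected(self):
        tau = np.arange(0, 4, dtype=float)
        curve = ACFCurve(lags=tau, values=np.ones(4), n_pairs=4 - np.arange(4))
        with pytest.raises(ValueError):
            fit_exponential(curve, window_override=(1.0, 3.0))


class TestAveraging:
    def _curve(self, values):
        n = len(values)
        return ACFCurve(lags=np.arange(n, dtype=float), values=np.asarray(values, float),
                        n_pairs=100 - np.arange(n))

    def _fit(self, valid=True):
        from dxblink import ExpFit
        return ExpFit(k=0.4, A=0.5, T=0.1, se_k=0.01, se_A=0.01, se_T=0.01,
                      chi_square=1.0, fit_window=(1.0, 10.0), valid=valid)

    def test_identical_curves_have_zero_stderr(self):
        c = self._curve([1, 0.9, 0.8])
        avg = average_acfs([c, c], [self._fit(), self._fit()])
        assert np.allclose(avg.mean, c.values)
        assert np.allclose(avg.stderr, 0.0)

    def test_textbook_standard_error(self):
        curves = [self._curve([1, v, 0.5]) for v in (0.9, 1.0, 1.1)]
        avg = average_acfs(curves, [self._fit()] * 3)
        assert avg.mean[1] == pytest.approx(1.0)
        assert avg.stderr[1] == pytest.approx(np.std([0.9, 1.0, 1.1], ddof=1) / math.sqrt(3))

    def test_invalid_fits_are_excluded(self):
        curves = [self._curve([1, 0.9, 0.8])] * 5
        fits = [self._fit(), self._fit(False), self._fit(), self._fit(), self._fit()]
        assert average_acfs(curves, fits).n_curves == 4

    def test_no_valid_curves_is_an_error(self):
        with pytest.raises(EmptySelectionError):
            average_acfs([self._curve([1, 0.9])], [self._fit(False)])


class TestFitAveraged:
    def test_uniform_weights_match_unweighted(self):
        tau = np.arange(0, 60, dtype=float)
        rngv = np.random.default_rng(3)
        vals = 0.4 + 0.6 * np.exp(-0.1 * tau) + rngv.normal(0, 0.01, 60)
        vals[0] = 1.0
        from dxblink import AveragedACF
        avg = AveragedACF(lags=tau, mean=vals, stderr=np.full(60, 0.02), n_curves=4)
        curve = ACFCurve(lags=tau, values=vals, n_pairs=600 - np.arange(60))
        fw = fit_averaged(avg, n_frames=600)
        fu = fit_exponential(curve, 0.10)
        assert fw.T == pytest.approx(fu.T, rel=1e-6)
        assert fw.k == pytest.approx(fu.k, rel=1e-6)

    def test_noiseless_exponential_chi_square_zero(self):
        tau = np.arange(0, 40, dtype=float)
        vals = 0.3 + 0.5 * np.exp(-0.2 * tau)
        from dxblink import AveragedACF
        avg = AveragedACF(lags=tau, mean=vals, stderr=np.full(40, 0.05), n_curves=2)
        f = fit_averaged(avg, n_frames=400)
        assert f.chi_square == pytest.approx(0.0, abs=1e-12)
        assert f.T == pytest.approx(0.2, rel=1e-8)

    def test_chi_square_matches_hand_sum(self):
        tau = np.arange(0, 30, dtype=float)
        rngv = np.random.default_rng(4)
        vals = 0.3 + 0.5 * np.exp(-0.2 * tau) + rngv.normal(0, 0.02, 30)
        stderr = np.full(30, 0.02)
        from dxblink import AveragedACF
        avg = AveragedACF(lags=tau, mean=vals, stderr=stderr, n_curves=3)
        f = fit_averaged(avg, n_frames=300)
        sel = (tau >= 1) & (tau <= math.floor(0.1 * 300) + 1)
        model = f.k + f.A * np.exp(-f.T * tau[sel])
        assert f.chi_square == pytest.approx(
            float(np.sum(((vals[sel] - model) / stderr[sel]) ** 2)))


class TestDecayRatio:
    def test_identity(self):
        from dxblink import ExpFit
        f = ExpFit(0.4, 0.5, 0.1, 0, 0, 0, 0, (1, 10), True)
        assert decay_ratio(f, f) == 1.0

    def test_invalid_fit_rejected(self):
        from dxblink import ExpFit
        good = ExpFit(0.4, 0.5, 0.1, 0, 0, 0, 0, (1, 10), True)
        bad = ExpFit(0.4, 0.5, 0.1, 0, 0, 0, 0, (1, 10), False)
        with pytest.raises(ValueError):
            decay_ratio(good, bad)


class TestPipeline:
    def test_deterministic_report(self, gapped_geometry, compact_ring):
        from dxblink import build_ring_mask
        mask = build_ring_mask(gapped_geometry, compact_ring, (50.0, 56.0))
        cfg = SimConfig(n_crystallites=6, D=5e-4, rocking_sigma=5e-3, peak_rate=2000.0,
                        background_rate=1.0, n_frames=300, exposure=0.4,
                        frame_interval=0.5, substeps_per_frame=4, init_spread=2e-2,
                        seed=31)
        stack = render_frames(cfg, gapped_geometry, compact_ring)
        r1 = dxb_pipeline(stack, mask)
        r2 = dxb_pipeline(stack, mask)
        assert r1.final_fit == r2.final_fit
        assert np.array_equal(r1.averaged.mean, r2.averaged.mean)
        assert r1.counts == r2.counts

    def test_decay_constant_grows_with_diffusion(self, gapped_geometry, compact_ring):
        from dxblink import build_ring_mask
        mask = build_ring_mask(gapped_geometry, compact_ring, (50.0, 56.0))
        ts = []
        for i, d in enumerate((1e-5, 4e-5)):
            cfg = SimConfig(n_crystallites=6, D=d, rocking_sigma=5e-3, peak_rate=2000.0,
                            background_rate=1.0, n_frames=400, exposure=0.4,
                            frame_interval=0.5, substeps_per_frame=4,
                            init_spread=2e-2, misorientation_bound=2e-2, seed=32)
            stack = render_frames(cfg, gapped_geometry, compact_ring)
            ts.append(dxb_pipeline(stack, mask).final_fit.T)
        assert ts[1] > ts[0]

    def test_lab_mode_normalisation_runs(self, compact_geometry, compact_ring,
                                         compact_mask):
        cfg = SimConfig(n_crystallites=4, D=5e-4, rocking_sigma=5e-3, peak_rate=2000.0,
                        background_rate=2.0, n_frames=200, exposure=0.4,
                        frame_interval=0.5, substeps_per_frame=4, init_spread=2e-2,
                        seed=33)
        stack = render_frames(cfg, compact_geometry, compact_ring)
        report = dxb_pipeline(stack, compact_mask, normalize=True)
        assert report.final_fit.T > 0
        bg = background_total(stack, compact_mask)
        assert len(bg) == stack.n_frames
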