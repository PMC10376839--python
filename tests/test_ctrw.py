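"""CTRW signal model, trace averaging and the two-step voxel fit."""

import numpy as np
import pytest

from crnn_dwi import (
    BValueScheme,
    CTRWParams,
    DWISeries,
    ctrw_signal,
    default_scheme,
    fit_ctrw_volume,
    fit_ctrw_voxel,
    fit_mono_exponential,
    mittag_leffler_e,
    simulate_dwi,
    trace_weighted,
)
from crnn_dwi.phantom import make_phantom_maps


class TestCtrwSignal:
    def test_b_zero_gives_one(self, scheme14):
        sig = ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 0.7, 0.8))
        assert sig[0] == 1.0

    def test_mono_exponential_limit(self, scheme14):
        sig = ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 1.0, 1.0))
        b = np.asarray(scheme14.bvalues)
        assert np.allclose(sig, np.exp(-b * 1e-3), atol=1e-12)

    def test_composes_mittag_leffler_with_power_law(self, scheme14):
        # frozen oracle: E_0.8(-(4000 * 1e-3)^0.9) from the 50-digit series
        sig = ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 0.8, 0.9))
        assert sig[-1] == pytest.approx(0.092614475427524773701, abs=1e-10)

    def test_non_increasing_in_b(self, scheme14):
        for a, be, dm in [(0.6, 1.0, 2e-3), (1.0, 0.6, 5e-4), (0.75, 0.85, 1.2e-3)]:
            sig = ctrw_signal(scheme14, CTRWParams(1.0, dm, a, be))
            assert np.all(np.diff(sig) <= 1e-12)

    def test_invalid_params_raise(self, scheme14):
        with pytest.raises(ValueError):
            ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 1.4, 0.8))
        with pytest.raises(ValueError):
            ctrw_signal(scheme14, CTRWParams(1.0, -1e-3, 0.8, 0.8))


class TestTraceWeighted:
    def test_identical_directions_pass_through(self, scheme14, rng):
        img = rng.random((8, 8))
        data = np.zeros((scheme14.n_frames, 1, 8, 8))
        data[0] = 1.0
        for f in range(1, scheme14.n_frames):
            data[f] = img
        series = DWISeries(data=data.astype(complex), scheme=scheme14)
        trace = trace_weighted(series)
        assert trace.scheme.n_bvalues == scheme14.n_bvalues
        for bi in range(1, trace.scheme.n_bvalues):
            assert np.allclose(trace.magnitude()[bi, 0], img)

    def test_geometric_mean_of_1_8_27_is_6(self, scheme14):
        data = np.ones((scheme14.n_frames, 1, 4, 4), dtype=complex)
        vals = (1.0, 8.0, 27.0)
        for d in range(3):
            data[scheme14.frame_index(1, d)] = vals[d]
        trace = trace_weighted(DWISeries(data=data, scheme=scheme14))
        assert np.allclose(trace.magnitude()[1], 6.0)

    def test_matches_elementwise_oracle_on_anisotropic_frames(self, scheme14, rng):
        data = rng.random((scheme14.n_frames, 2, 6, 6)).astype(complex)
        series = DWISeries(data=data, scheme=scheme14)
        trace = trace_weighted(series).magnitude()
        for bi in range(1, scheme14.n_bvalues):
            frames = [np.abs(data[scheme14.frame_index(bi, d)]) for d in range(3)]
            oracle = (frames[0] * frames[1] * frames[2]) ** (1.0 / 3.0)
            assert np.allclose(trace[bi], oracle, atol=1e-12)

    def test_b0_frame_unchanged(self, scheme14, rng):
        data = rng.random((scheme14.n_frames, 1, 5, 5)).astype(complex)
        trace = trace_weighted(DWISeries(data=data, scheme=scheme14))
        assert np.allclose(trace.magnitude()[0], np.abs(data[0]))


class TestMonoExponentialFit:
    def test_exact_model_recovered(self, scheme14):
        b = np.asarray(scheme14.bvalues)
        dm, ok = fit_mono_exponential(b, np.exp(-b * 1e-3))
        assert ok and dm == pytest.approx(1e-3, abs=1e-9)

    def test_constant_signal_clamps_to_lower_bound(self, scheme14):
        b = np.asarray(scheme14.bvalues)
        dm, ok = fit_mono_exponential(b, np.ones_like(b))
        assert ok and dm == 1e-6

    def test_matches_closed_form_regression_oracle(self, scheme14):
        b = np.asarray(scheme14.bvalues)
        sig = ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 0.8, 0.9))
        dm, ok = fit_mono_exponential(b, sig)
        # independent closed form: slope of ln(S) on -b through the origin
        oracle = np.dot(-b, np.log(sig)) / np.dot(b, b)
        assert ok and dm == pytest.approx(np.clip(oracle, 1e-6, 1e-2), rel=1e-12)

    def test_nonpositive_signals_excluded(self, scheme14):
        b = np.asarray(scheme14.bvalues)
        sig = np.exp(-b * 1e-3)
        sig[5] = 0.0  # dropped, not log(0)
        dm, ok = fit_mono_exponential(b, sig)
        assert ok and dm == pytest.approx(1e-3, abs=1e-9)

    def test_fewer_than_two_points_flags_failure(self):
        _, ok = fit_mono_exponential(np.array([0.0, 100.0]), np.array([1.0, -1.0]))
        assert not ok


class TestVoxelFit:
    def test_mono_exponential_self_consistency(self, scheme14):
        sig = ctrw_signal(scheme14, CTRWParams(1.0, 1e-3, 1.0, 1.0))
        p = fit_ctrw_voxel(scheme14, sig)
        assert p.alpha >= 0.99 and p.beta >= 0.99
        assert p.Dm == pytest.approx(1e-3, rel=0.01)
        assert p.converged and p.n_iter <= 80

    def test_forward_model_inversion(self, scheme14):
        truth = CTRWParams(1.0, 1.0e-3, 0.8, 0.9)
        sig = ctrw_signal(scheme14, truth)
        p = fit_ctrw_voxel(scheme14, sig)
        assert abs(p.alpha - 0.8) < 1e-3
        assert abs(p.beta - 0.9) < 1e-3
        # regenerating the signal from the fit reproduces the input
        regen = ctrw_signal(scheme14, p) * p.S0
        assert np.abs(regen - sig).max() < 1e-10

    @pytest.mark.parametrize("alpha", [0.6, 0.8, 1.0])
    @pytest.mark.parametrize("dm", [0.5e-3, 1e-3, 2e-3])
    def test_recovery_grid(self, scheme14, alpha, dm):
        for beta in (0.6, 0.8, 1.0):
            sig = ctrw_signal(scheme14, CTRWParams(1.0, dm, alpha, beta))
            p = fit_ctrw_voxel(scheme14, sig)
            assert abs(p.alpha - alpha) < 1e-3
            assert abs(p.beta - beta) < 1e-3
            assert abs(p.Dm - dm) / dm < 0.01
            assert p.n_iter <= 80

    def test_degenerate_signal_flagged_unconverged(self, scheme14):
        sig = np.zeros(scheme14.n_bvalues)
        sig[0] = 1.0  # only b = 0 usable
        p = fit_ctrw_voxel(scheme14, sig)
        assert not p.converged
        assert (p.alpha, p.beta) == (0.9, 0.9)  # initialization retained

    def test_rician_noise_bias_small_at_snr_50(self, scheme14, rng):
        """Magnitude (Rician) noise at SNR 50 leaves alpha/beta nearly unbiased."""
        truth = CTRWParams(1.0, 1.0e-3, 0.8, 0.9)
        clean = ctrw_signal(scheme14, truth)
        sigma = 1.0 / 50.0
        biases_a, biases_b = [], []
        for _ in range(500):
            noisy = np.abs(
                clean
                + sigma * rng.standard_normal(clean.size)
                + 1j * sigma * rng.standard_normal(clean.size)
            )
            p = fit_ctrw_voxel(scheme14, noisy)
            biases_a.append(p.alpha - truth.alpha)
            biases_b.append(p.beta - truth.beta)
        assert abs(np.mean(biases_a)) < 0.05
        assert abs(np.mean(biases_b)) < 0.05


class TestVolumeFit:
    def test_empty_mask_gives_zero_maps(self, scheme14):
        data = np.ones((scheme14.n_bvalues, 1, 8, 8), dtype=complex)
        trace = DWISeries(
            data=data, scheme=BValueScheme(scheme14.bvalues, ((1.0, 0.0, 0.0),))
        )
        maps = fit_ctrw_volume(trace, np.zeros((1, 8, 8), dtype=bool))
        assert maps.n_fitted == 0
        assert not maps.alpha_map.any()

    def test_uniform_volume_gives_constant_maps(self, scheme14):
        truth = CTRWParams(0.8, 1.2e-3, 0.75, 0.85)
        sig = ctrw_signal(scheme14, truth) * truth.S0
        data = np.broadcast_to(sig[:, None, None, None], (scheme14.n_bvalues, 1, 6, 6))
        trace = DWISeries(
            data=data.astype(complex),
            scheme=BValueScheme(scheme14.bvalues, ((1.0, 0.0, 0.0),)),
        )
        maps = fit_ctrw_volume(trace, np.ones((1, 6, 6), dtype=bool))
        assert np.allclose(maps.alpha_map, truth.alpha, atol=1e-3)
        assert np.allclose(maps.beta_map, truth.beta, atol=1e-3)
        assert np.allclose(maps.dm_map, truth.Dm, rtol=1e-2)
        assert maps.n_converged == maps.n_fitted == 36

    def test_two_region_phantom_recovers_both_parameter_sets(self, scheme14):
        maps_gt = make_phantom_maps(64, 64, 2, seed=11)
        series = simulate_dwi(maps_gt, scheme14, 0.0, seed=0)
        trace = trace_weighted(series)
        # subsampled mask keeps the test quick while covering both regions
        sub = np.zeros_like(maps_gt.fit_mask)
        sub[::5, ::5] = True
        fitted = fit_ctrw_volume(trace, (maps_gt.fit_mask & sub)[None])
        m = fitted.fit_mask
        assert np.abs(fitted.alpha_map - maps_gt.alpha_map[None])[m].max() < 1e-3
        assert np.abs(fitted.beta_map - maps_gt.beta_map[None])[m].max() < 1e-3
        rel = np.abs(fitted.dm_map[m] - maps_gt.dm_map[None][m]) / maps_gt.dm_map[None][m]
        assert rel.max() < 0.01
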