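import numpy as np
import pytest

from hp13c import (
    AcquisitionProtocol, DynamicImageSeries, GammaInput, InputlessKplModel,
    PKParams, auc_map, fit_kpl, fit_kpl_map, noise_normalize,
    simulate_epi_dynamics,
)


def _simulate(flips=(10.0, 30.0), kpl=0.05, tempres=3.0, amplitude=1.0):
    proto = AcquisitionProtocol(
        flips={"pyruvate": flips[0], "lactate": flips[1]},
        temporal_resolution=tempres)
    tc = simulate_epi_dynamics(proto, PKParams(kpl=kpl),
                               GammaInput(amplitude=amplitude))
    return tc


class TestInputlessFit:
    def test_noiseless_closed_loop_recovery(self):
        tc = _simulate()
        res = fit_kpl(tc.pyr, tc.lac, (10.0, 30.0), tc.times)
        assert res.converged
        assert res.kpl_hat == pytest.approx(0.05, abs=1e-3)

    @pytest.mark.parametrize("kpl", [0.01, 0.05, 0.1])
    def test_recovery_across_rates(self, kpl):
        tc = _simulate(kpl=kpl)
        res = fit_kpl(tc.pyr, tc.lac, (10.0, 30.0), tc.times)
        assert res.kpl_hat == pytest.approx(kpl, rel=2e-2)

    def test_monotone_in_true_rate(self):
        est = [fit_kpl(tc.pyr, tc.lac, (10.0, 30.0), tc.times).kpl_hat
               for tc in (_simulate(kpl=k)
                          for k in (0.01, 0.03, 0.05, 0.08, 0.12))]
        assert all(a < b for a, b in zip(est, est[1:]))

    def test_zero_lactate_pins_at_lower_bound(self):
        tc = _simulate(kpl=0.0)
        res = fit_kpl(tc.pyr, tc.lac, (10.0, 30.0), tc.times)
        assert res.kpl_hat == pytest.approx(0.0, abs=1e-6)
        assert res.pinned

    def test_scale_invariance(self):
        tc = _simulate()
        a = fit_kpl(tc.pyr, tc.lac, (10.0, 30.0), tc.times).kpl_hat
        b = fit_kpl(37.0 * tc.pyr, 37.0 * tc.lac, (10.0, 30.0), tc.times).kpl_hat
        assert b == pytest.approx(a, rel=1e-9)

    def test_flip_angle_correction(self):
        """Same kinetics at different flip schedules give matching estimates."""
        ests = []
        for flips in ((15.0, 30.0), (20.0, 50.0)):
            tc = _simulate(flips=flips)
            ests.append(fit_kpl(tc.pyr, tc.lac, flips, tc.times).kpl_hat)
        assert abs(ests[0] - ests[1]) / ests[0] < 0.05

    def test_bias_and_spread_vanish_with_noise(self, rng):
        tc = _simulate()
        for kpl in (0.01, 0.05, 0.1):
            tcx = _simulate(kpl=kpl)
            means, sds = [], []
            for noise in (2e-3, 2e-4):
                est = []
                for _ in range(40):
                    p = tcx.pyr + rng.normal(0, noise, tcx.pyr.size)
                    lac = tcx.lac + rng.normal(0, noise, tcx.lac.size)
                    est.append(fit_kpl(p, lac, (10.0, 30.0), tcx.times).kpl_hat)
                means.append(np.mean(est))
                sds.append(np.std(est))
            assert sds[1] < sds[0]
            assert abs(means[1] - kpl) < abs(means[0] - kpl) + 5e-4

    def test_all_zero_pyruvate_rejected(self):
        with pytest.raises(ValueError, match="pyruvate"):
            fit_kpl(np.zeros(5), np.ones(5), (10.0, 30.0), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            fit_kpl([1.0, 0.5], [0.1, 0.2], (10.0, 30.0), [0.0, 3.0])

    def test_model_results_interface(self):
        tc = _simulate()
        model = InputlessKplModel(tc.pyr, tc.lac, tc.times, 10.0, 30.0)
        res = model.fit()
        assert np.isfinite(res.bse) and res.bse > 0
        assert res.n_points_used == 18
        assert res.predict().shape == tc.lac.shape
        assert np.linalg.norm(res.resid) == pytest.approx(res.residual_norm,
                                                          abs=1e-12)
        text = res.summary()
        assert "k_PL estimate" in text and f"{res.kpl_hat:.5f}" in text

    def test_from_timecourse_constructor(self, epi_protocol, params, input_fn):
        tc = simulate_epi_dynamics(epi_protocol, params, input_fn)
        res = InputlessKplModel.from_timecourse(tc, epi_protocol).fit()
        assert res.kpl_hat == pytest.approx(params.kpl, abs=1e-3)


def _toy_series(noise_value=2.0, signal=100.0, kpl_pattern=None):
    """4x4 two-metabolite series with a constant noise strip."""
    tc = _simulate()
    n_t = tc.times.size
    data = np.zeros((2, n_t, 4, 4))
    data[0, :, 1:, :] = signal * tc.pyr[:, None, None]
    data[1, :, 1:, :] = signal * tc.lac[:, None, None]
    data[:, :, 0, :] = noise_value
    noise_mask = np.zeros((4, 4), bool)
    noise_mask[0, :] = True
    roi = np.zeros((4, 4), bool)
    roi[2:, 1:3] = True
    return DynamicImageSeries(
        data=data, times=tc.times, metabolites=("pyruvate", "lactate"),
        flips={"pyruvate": 10.0, "lactate": 30.0}, noise_mask=noise_mask), roi


class TestSeriesOperations:
    def test_noise_normalization_scales_by_region_mean(self):
        series, _ = _toy_series(noise_value=2.0)
        out, level = noise_normalize(series)
        assert level == pytest.approx(2.0)
        assert out.data[:, :, 0, :].mean() == pytest.approx(1.0)
        np.testing.assert_allclose(out.data, series.data / 2.0)

    def test_normalization_idempotent_up_to_scalar(self):
        series, _ = _toy_series()
        once, level1 = noise_normalize(series)
        twice, level2 = noise_normalize(once)
        assert level2 == pytest.approx(1.0)
        np.testing.assert_allclose(twice.data, once.data)

    def test_empty_noise_mask_rejected(self):
        series, _ = _toy_series()
        series.noise_mask = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match="noise mask"):
            noise_normalize(series)

    def test_zero_noise_mean_rejected(self):
        series, _ = _toy_series(noise_value=0.0)
        with pytest.raises(ValueError, match="zero"):
            noise_normalize(series)

    def test_auc_single_timepoint_is_frame(self):
        series, _ = _toy_series()
        single = DynamicImageSeries(
            data=series.data[:, :1], times=series.times[:1],
            metabolites=series.metabolites, flips=series.flips)
        aucs = auc_map(single)
        np.testing.assert_array_equal(aucs["pyruvate"], single.data[0, 0])

    def test_auc_time_permutation_invariant(self, rng):
        series, _ = _toy_series()
        perm = rng.permutation(series.times.size)
        shuffled = DynamicImageSeries(
            data=series.data[:, perm], times=np.sort(series.times),
            metabolites=series.metabolites, flips=series.flips)
        for met in series.metabolites:
            np.testing.assert_allclose(auc_map(series)[met],
                                       auc_map(shuffled)[met])

    def test_series_validation(self):
        with pytest.raises(ValueError, match="4-D"):
            DynamicImageSeries(data=np.zeros((2, 3, 4)), times=np.arange(3.0),
                               metabolites=("pyruvate", "lactate"), flips={})
        with pytest.raises(ValueError, match="non-negative"):
            DynamicImageSeries(data=-np.ones((2, 3, 4, 4)),
                               times=np.arange(3.0),
                               metabolites=("pyruvate", "lactate"), flips={})


class TestKplMap:
    def test_homogeneous_map_equals_roi_fit(self):
        series, roi = _toy_series()
        kpl_map, roi_res = fit_kpl_map(series, roi, noise_level=0.0)
        vals = kpl_map[roi]
        assert np.all(np.isfinite(vals))
        np.testing.assert_allclose(vals, roi_res.kpl_hat, rtol=1e-8)
        assert roi_res.kpl_hat == pytest.approx(0.05, abs=1e-3)

    def test_two_region_recovery(self):
        """Distinct rates in two regions are both recovered voxelwise."""
        tc_lo = _simulate(kpl=0.02)
        tc_hi = _simulate(kpl=0.10)
        n_t = tc_lo.times.size
        data = np.zeros((2, n_t, 4, 4))
        data[0, :, 1:, :2] = tc_lo.pyr[:, None, None]
        data[1, :, 1:, :2] = tc_lo.lac[:, None, None]
        data[0, :, 1:, 2:] = tc_hi.pyr[:, None, None]
        data[1, :, 1:, 2:] = tc_hi.lac[:, None, None]
        rng = np.random.default_rng(0)
        data = np.abs(data + rng.normal(0, 2e-4, data.shape))
        series = DynamicImageSeries(
            data=data, times=tc_lo.times,
            metabolites=("pyruvate", "lactate"),
            flips={"pyruvate": 10.0, "lactate": 30.0})
        roi = np.zeros((4, 4), bool)
        roi[1:, :] = True
        kpl_map, _ = fit_kpl_map(series, roi, noise_level=2e-4)
        lo = np.nanmean(kpl_map[1:, :2])
        hi = np.nanmean(kpl_map[1:, 2:])
        assert lo == pytest.approx(0.02, rel=0.10)
        assert hi == pytest.approx(0.10, rel=0.10)

    def test_low_snr_voxels_masked(self):
        series, roi = _toy_series(signal=100.0)
        # lactate too weak in one ROI voxel
        series.data[1, :, 2, 1] *= 1e-6
        kpl_map, _ = fit_kpl_map(series, roi, snr_floor=3.0, noise_level=1.0)
        assert np.isnan(kpl_map[2, 1])
        assert np.isfinite(kpl_map[3, 1])

    def test_empty_roi_rejected(self):
        series, _ = _toy_series()
        with pytest.raises(ValueError, match="empty ROI"):
            fit_kpl_map(series, np.zeros((4, 4), bool))
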