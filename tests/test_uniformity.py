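"""Regional/global uniformity, SNR, CNR, noise-vs-mAs fit."""

import dataclasses
import math

import numpy as np
import pytest

from tomoqa.acquisition import AcquisitionModel
from tomoqa.geometry import PhantomGeometry
from tomoqa.simulate import render, render_series
from tomoqa.uniformity import (CNR_BACKGROUND_ROI, GLOBAL_ROIS,
                               REGIONAL_ROIS, SNR_NOISE_ROI, SNR_SIGNAL_ROI,
                               check_roi_clear, cnr, fit_noise_vs_mas,
                               global_uniformity, regional_uniformity, snr)
from tomoqa.volume import ReconVolume


def flat_volume(level=1000.0, shape=(3, 400, 400)):
    return ReconVolume(np.full(shape, level, dtype=np.float32),
                       spacing=(1.0, 0.1, 0.1), origin=(-20.0, 45.0, 20.0))


SMALL_ROIS = ((-10.0, 55.0), (10.0, 55.0), (-10.0, 70.0), (10.0, 70.0),
              (0.0, 62.0))


class TestGlobalUniformity:
    def test_constant_slice_is_zero_percent(self):
        v = flat_volume()
        gu, _ = global_uniformity(v, 1, rois=SMALL_ROIS)
        assert gu == 0.0

    def test_injected_offset_recovered(self, rng):
        v = flat_volume()
        arr = v.intensities.copy()
        arr += rng.normal(0, 8.0, arr.shape).astype(np.float32)
        # shift the background level by +5% in the region of one ROI
        ys = v.y_positions
        xs = v.x_positions
        region = ((xs[None, :] - 10.0) ** 2
                  + (ys[:, None] - 55.0) ** 2) <= 7.0 ** 2
        arr[1][region] *= 1.05
        v.intensities = arr
        gu, _ = global_uniformity(v, 1, rois=SMALL_ROIS)
        assert gu == pytest.approx(5.0, abs=0.5)

    def test_scale_invariance_and_offset_decrease(self, rng):
        v = flat_volume()
        arr = v.intensities + rng.normal(0, 8.0, v.shape).astype(np.float32)
        arr[1, :200] += 20.0  # structured non-uniformity
        v.intensities = arr
        gu0, _ = global_uniformity(v, 1, rois=SMALL_ROIS)
        scaled = dataclasses.replace(v)
        scaled.intensities = arr * 3.0
        gu_scaled, _ = global_uniformity(scaled, 1, rois=SMALL_ROIS)
        assert gu_scaled == pytest.approx(gu0, rel=1e-4)  # float32 rounding
        shifted = dataclasses.replace(v)
        shifted.intensities = arr + 500.0
        gu_shifted, _ = global_uniformity(shifted, 1, rois=SMALL_ROIS)
        assert gu_shifted < gu0

    def test_noise_only_vanishes_as_noise_shrinks(self, rng):
        values = []
        for sd in (8.0, 0.5):
            v = flat_volume()
            v.intensities = (v.intensities
                             + rng.normal(0, sd, v.shape)).astype(np.float32)
            values.append(global_uniformity(v, 1, rois=SMALL_ROIS)[0])
        assert values[1] < values[0]
        assert values[1] < 0.05

    def test_roi_out_of_field_rejected(self):
        v = flat_volume()
        with pytest.raises(ValueError, match="outside"):
            global_uniformity(v, 1, rois=((500.0, 500.0),) + SMALL_ROIS[1:])


class TestRegionalUniformity:
    def test_means_track_z_ramp(self):
        v = flat_volume(shape=(5, 400, 400))
        grad = np.arange(5, dtype=np.float32)[:, None, None] * 10.0
        v.intensities = v.intensities + grad
        rois = {"anterior": (0.0, 62.0)}
        series = regional_uniformity(v, rois=rois, radius=8.0)["anterior"]
        means = [s.mean for s in series]
        np.testing.assert_allclose(np.diff(means), 10.0, atol=1e-3)

    def test_sd_matches_injected_noise(self, geom, default_volume):
        series = regional_uniformity(default_volume, geometry=geom)
        injected = default_volume.metadata["noise_sd"]
        for stats in series.values():
            mid = stats[len(stats) // 2]
            assert mid.sd == pytest.approx(injected, rel=0.15)

    def test_roi_placement_verified_against_objects(self, geom):
        v = flat_volume()
        with pytest.raises(ValueError, match="overlaps"):
            regional_uniformity(v, geometry=geom,
                                rois={"bad": (0.0, 30.0)})  # on the square

    def test_default_rois_clear_of_all_objects(self, geom):
        for c in REGIONAL_ROIS.values():
            check_roi_clear(geom, c, 10.0)
        for c in GLOBAL_ROIS:
            check_roi_clear(geom, c, 5.0)
        for c in (SNR_SIGNAL_ROI, SNR_NOISE_ROI):
            check_roi_clear(geom, c, 5.0)
        check_roi_clear(geom, CNR_BACKGROUND_ROI, 1.5)

    def test_uniformity_with_and_without_objects_agrees(self, geom,
                                                        default_acq):
        # multi-purpose phantom vs object-free render of the same field
        v_obj = render(geom, default_acq)
        empty = PhantomGeometry(x_range=geom.x_range, y_range=geom.y_range)
        v_uni = render(empty, default_acq)
        k = v_obj.shape[0] // 2
        gu_obj, _ = global_uniformity(v_obj, k, geometry=geom)
        gu_uni, _ = global_uniformity(v_uni, k)
        assert abs(gu_obj - gu_uni) <= 0.5  # percentage points


class TestSNRandCNR:
    def test_snr_definition(self, rng):
        v = flat_volume(level=100.0)
        noise = rng.normal(0, 10.0, v.shape).astype(np.float32)
        v.intensities = v.intensities + noise
        res = snr(v, 1, signal_roi=(0.0, 62.0), noise_roi=(10.0, 55.0),
                  radius=8.0)
        assert res.value == pytest.approx(10.0, rel=0.1)

    def test_noiseless_snr_flagged_infinite(self):
        v = flat_volume()
        res = snr(v, 1, signal_roi=(0.0, 62.0), noise_roi=(10.0, 55.0))
        assert math.isinf(res.value)
        assert res.flagged_infinite

    def test_snr_scales_with_sqrt_mas(self, geom):
        vols = render_series(geom, AcquisitionModel(seed=7), [50.0, 200.0])
        k = vols[0].shape[0] // 2
        r = snr(vols[1], k, geometry=geom).value \
            / snr(vols[0], k, geometry=geom).value
        assert r == pytest.approx(2.0, rel=0.1)

    def test_cnr_definition(self, geom, default_volume):
        res = cnr(default_volume, geom)
        expected_net = 0.2 * 1000.0  # aluminium square contrast, 2 mm thick
        assert res.net_signal == pytest.approx(expected_net, rel=0.15)
        assert res.value == pytest.approx(res.net_signal / res.background.sd,
                                          rel=1e-9)

    def test_cnr_zero_for_equal_means(self, geom):
        flat = PhantomGeometry(x_range=geom.x_range, y_range=geom.y_range,
                               al_square=dataclasses.replace(
                                   geom.al_square, contrast=0.0))
        v = render(flat, AcquisitionModel(noise_base_sd=0.0))
        assert cnr(v, flat).value == 0.0

    def test_cnr_errors_when_square_region_missing(self, geom):
        # a volume that does not reach the square's slices
        sub = PhantomGeometry(x_range=geom.x_range, y_range=geom.y_range,
                              overall_thickness=10.0, al_square=None)
        v = render(sub, AcquisitionModel(noise_base_sd=0.0))
        with pytest.raises(ValueError, match="square"):
            cnr(v, geom)

    def test_cnr_scales_with_sqrt_mas(self, geom):
        vols = render_series(geom, AcquisitionModel(seed=8), [50.0, 100.0])
        r = cnr(vols[1], geom).value / cnr(vols[0], geom).value
        assert r == pytest.approx(np.sqrt(2.0), rel=0.1)


class TestNoiseFit:
    def test_exact_power_law_recovered(self):
        mas = np.array([25.0, 50.0, 100.0, 200.0])
        fit = fit_noise_vs_mas(list(zip(mas, 50.0 * mas ** -0.5)))
        assert fit.exponent == pytest.approx(-0.5, abs=1e-12)
        assert fit.amplitude == pytest.approx(50.0, rel=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_constant_sd_gives_zero_exponent(self):
        fit = fit_noise_vs_mas([(25.0, 7.0), (50.0, 7.0), (100.0, 7.0)])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_simulated_sweep_recovers_half_power(self, geom):
        exps = []
        for seed in range(3):
            vols = render_series(geom, AcquisitionModel(seed=seed),
                                 [25.0, 50.0, 100.0, 200.0])
            k = vols[0].shape[0] // 2
            pts = []
            for m, v in zip([25.0, 50.0, 100.0, 200.0], vols):
                stats = regional_uniformity(v, geometry=geom)
                pts.append((m, stats["anterior"][k].sd))
            exps.append(fit_noise_vs_mas(pts).exponent)
        assert np.mean(exps) == pytest.approx(-0.5, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_noise_vs_mas([(25.0, 5.0), (50.0, 4.0)])
        with pytest.raises(ValueError):
            fit_noise_vs_mas([(25.0, -5.0), (50.0, 4.0), (100.0, 3.0)])
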